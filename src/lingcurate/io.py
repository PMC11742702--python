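"""Reading and writing the workflow's file formats.

Three families of formats:

* **flat matrix CSV** — first column the taxon id, remaining columns
  feature ids; cells are state tokens or the reserved ``?`` / ``NA``
  literals (both configurable, since input dialects vary);
* **curation metadata** — the two-table dialect driving curation:
  ``decisions-log.csv`` (one row per modification, with a unique id, type,
  operation, input/output features and rationale; statistical expectations
  share the table) and ``feature-recode-patterns.csv`` (one row per
  feature, linking it to the modifications that produce/consume it);
* **CLDF StructureDataset** — languages / parameters / codes / values /
  modifications tables plus a JSON metadata descriptor. Unknown cells are
  simply absent from the values table; not-applicable cells are explicit
  ``NA`` values with a per-parameter NA code, so the distinction survives
  round-trips. All row orders are sorted, making output byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    NOT_APPLICABLE,
    UNKNOWN,
    FeatureDef,
    TraitMatrix,
    TraitMatrixError,
)
from .dependencies import Expectation
from .recode import Modification, RecodePlan

CLDF_FILES = ("languages.csv", "parameters.csv", "codes.csv", "values.csv",
              "modifications.csv", "StructureDataset-metadata.json")


# -- flat matrix CSV -------------------------------------------------------


def write_matrix_csv(m: TraitMatrix, path: str | Path,
                     unknown: str = UNKNOWN, na: str = NOT_APPLICABLE) -> None:
    df = m.data.copy()
    if unknown != UNKNOWN or na != NOT_APPLICABLE:
        df = df.replace({UNKNOWN: unknown, NOT_APPLICABLE: na})
    df.index.name = "taxon"
    df.to_csv(path)


def read_matrix_csv(path: str | Path, features=None,
                    unknown: str = UNKNOWN, na: str = NOT_APPLICABLE) -> TraitMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df = df.replace({unknown: UNKNOWN, na: NOT_APPLICABLE, "": UNKNOWN})
    return TraitMatrix(df, features)


def write_taxonomy_csv(tax: pd.DataFrame, path: str | Path) -> None:
    out = tax.copy()
    out.index.name = "id"
    out.to_csv(path)


def read_taxonomy_csv(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, index_col=0, dtype={"lineage": str, "macroarea": str})
    tax.index = tax.index.astype(str)
    return tax


# -- curation metadata dialect ---------------------------------------------


def write_decisions_log(plan: RecodePlan, path: str | Path,
                        extra_columns: pd.DataFrame | None = None) -> None:
    rows = []
    for mod in plan.modifications:
        rows.append({
            "modification.ID": mod.id,
            "type": mod.mtype,
            "operation": mod.op_kind,
            "input.features": ";".join(mod.input_features),
            "output.features": ";".join(mod.output_features),
            "params": json.dumps(mod.params, sort_keys=True),
            "rationale": mod.rationale,
        })
    df = pd.DataFrame(rows, columns=["modification.ID", "type", "operation",
                                     "input.features", "output.features",
                                     "params", "rationale"])
    if extra_columns is not None:
        df = df.merge(extra_columns, how="left", left_on="modification.ID",
                      right_index=True)
    df.to_csv(path, index=False)


def read_decisions_log(path: str | Path) -> RecodePlan:
    """Parse a decisions log; free statistics columns are ignored."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mods = []
    for r in df.to_dict("records"):
        mods.append(Modification(
            id=r["modification.ID"],
            mtype=r["type"],
            op_kind=r["operation"],
            input_features=[f for f in r["input.features"].split(";") if f],
            output_features=[f for f in r["output.features"].split(";") if f],
            params=json.loads(r["params"]) if r.get("params") else {},
            rationale=r.get("rationale", ""),
        ))
    return RecodePlan(mods)


def write_recode_patterns(m: TraitMatrix, plan: RecodePlan,
                          path: str | Path) -> None:
    links = plan.feature_table()
    links = links.set_index("feature") if len(links) else pd.DataFrame(
        columns=["produced_by", "consumed_by"])
    rows = []
    for fid in sorted(m.feature_ids):
        f = m.features[fid]
        rows.append({
            "feature": fid,
            "label": f.label,
            "states": ";".join(f.states),
            "group": f.group,
            "provenance": f.provenance,
            "produced_by": links["produced_by"].get(fid, ""),
            "consumed_by": links["consumed_by"].get(fid, ""),
            "known.remaining.dependencies": ";".join(
                f.known_remaining_dependencies),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_expectations_csv(path: str | Path) -> list[Expectation]:
    """Expectations in the decisions-log dialect (type THEN/OR/AND)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Expectation(
            id=r["modification.ID"], etype=r["type"],
            side1=(r["feature1"], r["state1"]),
            side2=(r["feature2"], r["state2"]),
            motivation=r.get("motivation", ""),
        )
        for r in df.to_dict("records")
    ]


def write_expectations_csv(expectations: list[Expectation],
                           path: str | Path,
                           results: pd.DataFrame | None = None) -> None:
    rows = [
        {"modification.ID": e.id, "type": e.etype,
         "feature1": e.side1[0], "state1": e.side1[1],
         "feature2": e.side2[0], "state2": e.side2[1],
         "motivation": e.motivation}
        for e in expectations
    ]
    df = pd.DataFrame(rows)
    if results is not None:
        df = df.merge(results, how="left", left_on="modification.ID",
                      right_on="expectation", suffixes=("", "_result"))
        df = df.drop(columns=[c for c in ("expectation", "type_result")
                              if c in df.columns])
    df.to_csv(path, index=False)


# -- CLDF StructureDataset -------------------------------------------------


def _metadata_descriptor() -> dict:
    def table(url, columns):
        return {"url": url,
                "tableSchema": {"columns": [{"name": c} for c in columns]}}

    return {
        "dc:conformsTo": "http://cldf.clld.org/v1.0/terms.rdf#StructureDataset",
        "tables": [
            table("languages.csv",
                  ["ID", "Name", "Lineage", "Macroarea", "Latitude",
                   "Longitude"]),
            table("parameters.csv",
                  ["ID", "Name", "Group", "Provenance",
                   "Known_Remaining_Dependencies"]),
            table("codes.csv", ["ID", "Parameter_ID", "Name"]),
            table("values.csv",
                  ["ID", "Language_ID", "Parameter_ID", "Value", "Code_ID"]),
            table("modifications.csv",
                  ["ID", "Type", "Operation", "Input_Features",
                   "Output_Features", "Params", "Rationale"]),
        ],
    }


def write_cldf(m: TraitMatrix, tax: pd.DataFrame, path: str | Path,
               plan: RecodePlan | None = None) -> Path:
    """Emit the six-file bundle; deterministic (sorted) row order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    langs = []
    for tid in sorted(m.taxa):
        row = tax.loc[tid] if tid in tax.index else None
        langs.append({
            "ID": tid,
            "Name": tid,
            "Lineage": "" if row is None else row.get("lineage", ""),
            "Macroarea": "" if row is None else row.get("macroarea", ""),
            "Latitude": "" if row is None else row.get("lat", ""),
            "Longitude": "" if row is None else row.get("lon", ""),
        })
    pd.DataFrame(langs).to_csv(path / "languages.csv", index=False)

    params, codes = [], []
    for fid in sorted(m.feature_ids):
        f = m.features[fid]
        params.append({
            "ID": fid, "Name": f.label or fid,
            "Group": f.group + (f"_{f.sub_flag}" if f.sub_flag else ""),
            "Provenance": f.provenance,
            "Known_Remaining_Dependencies": ";".join(
                f.known_remaining_dependencies),
        })
        for s in f.states:
            codes.append({"ID": f"{fid}-{s}", "Parameter_ID": fid, "Name": s})
        codes.append({"ID": f"{fid}-NA", "Parameter_ID": fid,
                      "Name": NOT_APPLICABLE})
    pd.DataFrame(params).to_csv(path / "parameters.csv", index=False)
    pd.DataFrame(codes).to_csv(path / "codes.csv", index=False)

    values = []
    k = 0
    for tid in sorted(m.taxa):
        for fid in sorted(m.feature_ids):
            v = m.data.at[tid, fid]
            if v == UNKNOWN:
                continue  # unknown cells are simply absent
            k += 1
            values.append({
                "ID": f"v{k}", "Language_ID": tid, "Parameter_ID": fid,
                "Value": v, "Code_ID": f"{fid}-{v}",
            })
    pd.DataFrame(values, columns=["ID", "Language_ID", "Parameter_ID",
                                  "Value", "Code_ID"]
                 ).to_csv(path / "values.csv", index=False)

    mods = []
    if plan is not None:
        for mod in plan.modifications:
            mods.append({
                "ID": mod.id, "Type": mod.mtype, "Operation": mod.op_kind,
                "Input_Features": ";".join(mod.input_features),
                "Output_Features": ";".join(mod.output_features),
                "Params": json.dumps(mod.params, sort_keys=True),
                "Rationale": mod.rationale,
            })
    pd.DataFrame(mods, columns=["ID", "Type", "Operation", "Input_Features",
                                "Output_Features", "Params", "Rationale"]
                 ).to_csv(path / "modifications.csv", index=False)

    (path / "StructureDataset-metadata.json").write_text(
        json.dumps(_metadata_descriptor(), indent=2, sort_keys=True) + "\n")
    return path


def read_cldf(path: str | Path
              ) -> tuple[TraitMatrix, pd.DataFrame, RecodePlan | None]:
    """Load a bundle with referential-integrity checks.

    Missing value rows become unknown cells; explicit NA codes become
    not-applicable. Violations (values referencing unknown languages,
    parameters or codes) raise an error listing the offending rows.
    """
    path = Path(path)
    if not (path / "StructureDataset-metadata.json").exists():
        raise FileNotFoundError(
            f"no StructureDataset-metadata.json under {path}")
    langs = pd.read_csv(path / "languages.csv", dtype=str,
                        keep_default_na=False)
    params = pd.read_csv(path / "parameters.csv", dtype=str,
                         keep_default_na=False)
    codes = pd.read_csv(path / "codes.csv", dtype=str, keep_default_na=False)
    values = pd.read_csv(path / "values.csv", dtype=str, keep_default_na=False)

    problems = []
    known_lang = set(langs["ID"])
    known_param = set(params["ID"])
    code_param = dict(zip(codes["ID"], codes["Parameter_ID"]))
    for i, r in values.iterrows():
        if r["Language_ID"] not in known_lang:
            problems.append(f"values row {i}: unknown language {r['Language_ID']!r}")
        if r["Parameter_ID"] not in known_param:
            problems.append(f"values row {i}: unknown parameter {r['Parameter_ID']!r}")
        if code_param.get(r["Code_ID"]) != r["Parameter_ID"]:
            problems.append(
                f"values row {i}: code {r['Code_ID']!r} does not belong to "
                f"parameter {r['Parameter_ID']!r}")
    if problems:
        raise TraitMatrixError(
            "referential integrity violations:\n" + "\n".join(problems))

    fdefs = {}
    for r in params.to_dict("records"):
        fid = r["ID"]
        states = tuple(codes.loc[(codes["Parameter_ID"] == fid)
                                 & (codes["Name"] != NOT_APPLICABLE), "Name"])
        group, _, sub = r.get("Group", "grammar").partition("_")
        fdefs[fid] = FeatureDef(
            id=fid, states=states, label=r.get("Name", ""),
            group=group or "grammar", sub_flag=sub or None,
            provenance=r.get("Provenance", ""),
            known_remaining_dependencies=[
                d for d in r.get("Known_Remaining_Dependencies", "").split(";")
                if d],
        )

    data = pd.DataFrame(UNKNOWN, index=sorted(known_lang),
                        columns=sorted(known_param), dtype=object)
    for r in values.to_dict("records"):
        data.at[r["Language_ID"], r["Parameter_ID"]] = r["Value"]
    matrix = TraitMatrix(data, fdefs)

    tax = pd.DataFrame({
        "lineage": langs["Lineage"].values,
        "macroarea": langs["Macroarea"].values,
        "lat": pd.to_numeric(langs["Latitude"], errors="coerce").values,
        "lon": pd.to_numeric(langs["Longitude"], errors="coerce").values,
    }, index=pd.Index(langs["ID"], name="id"))

    plan = None
    mods_path = path / "modifications.csv"
    if mods_path.exists():
        mods_df = pd.read_csv(mods_path, dtype=str, keep_default_na=False)
        if len(mods_df):
            plan = RecodePlan([
                Modification(
                    id=r["ID"], mtype=r["Type"], op_kind=r["Operation"],
                    input_features=[f for f in r["Input_Features"].split(";") if f],
                    output_features=[f for f in r["Output_Features"].split(";") if f],
                    params=json.loads(r["Params"]) if r["Params"] else {},
                    rationale=r["Rationale"],
                )
                for r in mods_df.to_dict("records")
            ])
    return matrix, tax, plan
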