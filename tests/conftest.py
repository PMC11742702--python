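import numpy as np
import pandas as pd
import pytest

from lingcurate.core import FeatureDef, Taxon, TraitMatrix, taxonomy_frame
from lingcurate.recode import Modification, RecodePlan


def make_matrix(rows, features=None):
    """Build a TraitMatrix from {taxon: {feature: token}}."""
    df = pd.DataFrame.from_dict(rows, orient="index").fillna("?")
    return TraitMatrix(df, features)


def binary_features(fids):
    return {f: FeatureDef(id=f, states=("1", "0")) for f in fids}


def isolate_taxonomy(taxa, area="Africa"):
    """Every taxon its own lineage: neutralizes the redundancy term."""
    return taxonomy_frame([Taxon(t, lineage=t, macroarea=area) for t in taxa])


def symmetric_taxonomy(n_lineages=20, taxa_per_lineage=1, areas=None):
    """Balanced taxonomy: n lineages per area, fixed taxa per lineage."""
    from lingcurate.core import MACROAREAS

    areas = areas or MACROAREAS
    taxa = []
    for area in areas:
        for li in range(n_lineages):
            for ti in range(taxa_per_lineage):
                taxa.append(Taxon(
                    id=f"{area[:3]}_{li:02d}_{ti}",
                    lineage=f"{area[:3]}_fam{li:02d}", macroarea=area))
    return taxonomy_frame(taxa)


@pytest.fixture
def gender_fixture():
    """Six taxa, three binary gender-manifestation features + recode plan.

    The plan derives a presence meta-feature and conditions each
    manifestation feature on it, so taxa known to lack the phenomenon get
    not-applicable on every conditioned column.
    """
    rows = {
        "t1": {"g1": "1", "g2": "0", "g3": "0"},
        "t2": {"g1": "0", "g2": "0", "g3": "0"},
        "t3": {"g1": "0", "g2": "?", "g3": "0"},
        "t4": {"g1": "1", "g2": "1", "g3": "0"},
        "t5": {"g1": "?", "g2": "?", "g3": "?"},
        "t6": {"g1": "0", "g2": "0", "g3": "?"},
    }
    m = make_matrix(rows, binary_features(["g1", "g2", "g3"]))
    mods = [
        Modification("L-GEN-1", "logical", "merge_meta",
                     ["g1", "g2", "g3"], ["gender_m"],
                     {"present": "1", "absent": "0"},
                     rationale="presence of the phenomenon"),
    ]
    for g in ("g1", "g2", "g3"):
        mods.append(Modification(
            f"L-GEN-{g}", "logical", "condition", [g], [f"{g}c"],
            {"condition": "gender_m", "allowed": ["1"],
             "mode": "conservative"}))
    return m, RecodePlan(mods)
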