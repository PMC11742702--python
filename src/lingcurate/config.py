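"""Curation configuration: every threshold of the workflow in one place.

Defaults are the published project choices; all are overridable per run
(from Python, a YAML/JSON file or the command line).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class CurationConfig:
    """Tunable thresholds of the curation workflow.

    Attributes
    ----------
    min_coding : int
        A feature must be coded for at least this many taxa to be included
        (default 100).
    min_variability : int
        The second-most-frequent state of a feature must be attested in at
        least this many taxa (default 3).
    overlap_ratio : float
        Feature-level coded-overlap prefilter for dependency testing: the
        better-coded feature of a pair must have at least this fraction of
        its taxa coded for the other feature (default 0.30).
    applicability_ratio : float
        Minimum per-sample applicability ratio; samples below it are dropped
        from a test (default 1/3).
    min_valid_samples : int
        Minimum number of surviving diversity samples for a testable
        expectation (default 20).
    d_threshold : float
        Paired Cohen's D above which an effect counts as very strong
        (default 1.3).
    exception_threshold : float
        Acting requires mean + sd of the conditional (exception) probability
        below this (default 0.2).
    liberal_prevalence : float
        Conditioning switches from conservative to liberal when the
        condition state covers at least this fraction of coded taxa
        (default 0.90).
    n_per_area : int
        Lineages sampled per macroarea in a diversity sample (default 20).
    n_samples : int
        Number of diversity samples per batch (default 500).
    min_features_coded : int
        Sampling eligibility: a taxon must be coded for at least this many
        features (default 0; sparse multi-source setups use 10).
    unknown_token, na_token : str
        Reserved literals used in flat CSV serialization.
    """

    min_coding: int = 100
    min_variability: int = 3
    overlap_ratio: float = 0.30
    applicability_ratio: float = 1.0 / 3.0
    min_valid_samples: int = 20
    d_threshold: float = 1.3
    exception_threshold: float = 0.2
    liberal_prevalence: float = 0.90
    n_per_area: int = 20
    n_samples: int = 500
    min_features_coded: int = 0
    unknown_token: str = "?"
    na_token: str = "NA"

    @classmethod
    def from_file(cls, path: str | Path) -> "CurationConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = CurationConfig()
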