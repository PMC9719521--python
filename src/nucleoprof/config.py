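"""YAML configuration with the pipeline's standard defaults.

Every numeric convention of the pipeline lives here: the fragment-length
window, the bin grid, the smoothing filter, the feature windows, the
outlier threshold and the mappability cutoff.  A short hash of the
serialized configuration is stamped into outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


@dataclass
class ClassifierSettings:
    n_iterations: int = 1000
    pca_variance_target: Optional[float] = 0.80
    c_grid: Tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    cv_folds: int = 10
    resample_unit: str = "sample"
    first_timepoint_only: bool = False


@dataclass
class PipelineConfig:
    fragment_range: Tuple[int, int] = (100, 200)
    window: int = 5000
    bin_size: int = 15
    smoothing_bp: int = 165
    smoothing_order: int = 3
    central_halfwidth: int = 30
    mean_halfwidth: int = 1000
    fft_window: int = 960
    fft_term: int = 10
    outlier_sd: float = 10.0
    mappability_threshold: float = 1.0
    gc_length_range: Tuple[int, int] = (15, 500)
    gc_correction: bool = True
    mappability_correction: bool = False
    cna_correction: bool = False
    seed: int = 0
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)

    def __post_init__(self):
        if self.bin_size <= 0 or self.window < self.bin_size:
            raise ValueError("window must cover at least one positive-width bin")
        if not (0 < self.mappability_threshold <= 1):
            raise ValueError("mappability_threshold must lie in (0, 1]")
        if self.fragment_range[0] > self.fragment_range[1]:
            raise ValueError("fragment_range must be (low, high)")

    # ----------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fragment_range"] = list(self.fragment_range)
        d["gc_length_range"] = list(self.gc_length_range)
        d["classifier"]["c_grid"] = list(self.classifier.c_grid)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def load_validate_config(path) -> PipelineConfig:
    """Load YAML, rejecting unknown keys with a clear error."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise FileNotFoundError(f"configuration file not found: {path}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    clf = data.pop("classifier", None)
    kwargs = dict(data)
    for key in ("fragment_range", "gc_length_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if clf is not None:
        known_clf = {f.name for f in dataclasses.fields(ClassifierSettings)}
        unknown = set(clf) - known_clf
        if unknown:
            raise ValueError(f"unknown classifier configuration keys: {sorted(unknown)}")
        if "c_grid" in clf:
            clf["c_grid"] = tuple(clf["c_grid"])
        kwargs["classifier"] = ClassifierSettings(**clf)
    return PipelineConfig(**kwargs)
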