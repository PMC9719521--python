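"""Three-feature quantification of composite nucleosome profiles.

A trimmed, normalized composite profile is summarized by:

* **central coverage** — mean profile value within ±30 bp of the site;
  low values mean strong central protection loss (open chromatin).
* **mean coverage** — mean value within ±1000 bp.
* **amplitude** — modulus of term 10 of the unnormalized forward DFT over
  the 128 bins spanning ±960 bp.  Term 10 corresponds to a 192 bp period,
  matching the ~190 bp spacing of phased nucleosomes flanking an active
  site; a flat profile has amplitude 0.

Feature matrices assemble (sample x site-list x feature) values with
per-sample metadata for the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .profiling import BIN_SIZE, CompositeProfile

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("central_coverage", "mean_coverage", "amplitude")

FFT_WINDOW = 960
FFT_TERM = 10
CENTRAL_HALFWIDTH = 30
MEAN_HALFWIDTH = 1000


@dataclass
class ProfileFeatures:
    central_coverage: float
    mean_coverage: float
    amplitude: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "central_coverage": self.central_coverage,
            "mean_coverage": self.mean_coverage,
            "amplitude": self.amplitude,
        }


def central_coverage(profile: CompositeProfile, halfwidth: int = CENTRAL_HALFWIDTH) -> float:
    """Mean over unmasked bins whose centers lie within ±halfwidth bp."""
    sel = (np.abs(profile.offsets) <= halfwidth) & ~profile.mask
    if not sel.any():
        raise ValueError("feature undefined: all central bins masked")
    return float(profile.values[sel].mean())


def mean_coverage(profile: CompositeProfile, halfwidth: int = MEAN_HALFWIDTH) -> float:
    """Mean over unmasked bins whose centers lie within ±halfwidth bp."""
    sel = (np.abs(profile.offsets) <= halfwidth) & ~profile.mask
    if not sel.any():
        raise ValueError("feature undefined: all bins masked")
    return float(profile.values[sel].mean())


def fft_amplitude(
    profile: CompositeProfile,
    window: int = FFT_WINDOW,
    term: int = FFT_TERM,
    bin_size: int = BIN_SIZE,
) -> float:
    """Modulus of DFT term ``term`` over the bins starting in [-window, window).

    Convention (frozen): unnormalized forward transform of the 128-bin
    vector; all window bins must be unmasked.
    """
    starts = profile.offsets - (bin_size - 1) / 2 - 0.5
    sel = (starts >= -window) & (starts < window)
    if profile.mask[sel].any():
        raise ValueError("feature undefined: masked bins inside the FFT window")
    v = profile.values[sel]
    return float(np.abs(np.fft.fft(v)[term]))


def profile_features(profile: CompositeProfile) -> ProfileFeatures:
    return ProfileFeatures(
        central_coverage(profile), mean_coverage(profile), fft_amplitude(profile)
    )


@dataclass
class FeatureMatrix:
    """Samples x (site list, feature) matrix with aligned metadata.

    ``X`` has one column per (site list, feature) pair in deterministic
    order (site list name sorted, then central/mean/amplitude); ``metadata``
    carries label, tumor fraction, patient id and optional timepoint per
    row, aligned by index.
    """

    X: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if not self.X.index.equals(self.metadata.index):
            raise ValueError("feature matrix and metadata indexes differ")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def to_tsv(self, features_path, metadata_path) -> None:
        self.X.to_csv(features_path, sep="\t")
        self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, features_path, metadata_path) -> "FeatureMatrix":
        X = pd.read_csv(features_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(X, meta.loc[X.index])


def assemble_feature_matrix(
    per_sample: Mapping[str, Mapping[str, Optional[ProfileFeatures]]],
    metadata: pd.DataFrame,
) -> FeatureMatrix:
    """Assemble features across samples and site lists into one matrix.

    ``per_sample[sample][site_list]`` holds the ProfileFeatures for that
    pair, or None when profiling failed; samples with any missing profile
    are dropped with a log entry so the matrix has no missing cells.
    """
    site_lists = sorted({sl for d in per_sample.values() for sl in d})
    columns = [f"{sl}.{feat}" for sl in site_lists for feat in FEATURE_NAMES]
    rows, index = [], []
    for sample, feats in per_sample.items():
        if any(feats.get(sl) is None for sl in site_lists):
            missing = [sl for sl in site_lists if feats.get(sl) is None]
            logger.warning("sample %s dropped: missing profiles for %s", sample, missing)
            continue
        row = []
        for sl in site_lists:
            f = feats[sl]
            row.extend([f.central_coverage, f.mean_coverage, f.amplitude])
        rows.append(row)
        index.append(sample)
    X = pd.DataFrame(rows, index=index, columns=columns)
    meta = metadata.loc[index]
    return FeatureMatrix(X, meta)
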