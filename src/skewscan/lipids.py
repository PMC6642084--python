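"""DGTS/PC lipid ratios and sequence-marker validation.

DGTS (diacylglyceryl-trimethylhomoserine) is a phosphorus-free betaine lipid
that can substitute for phosphatidylcholine (PC) in P-limited environments;
presence of a DUF3419-family transcript is used as a sequence marker for the
DGTS synthase. This module computes per-sample DGTS/PC abundance ratios from
mass-spectrometric AUC tables and tests the association between the sequence
marker and detectable DGTS with the exact 2x2 Fisher test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, ParameterError
from .fisher import concordance_from_counts
from .hits import PresenceMatrix

log = logging.getLogger(__name__)

LIPID_CLASSES = ("PC", "DGTS")
LIPID_COLUMNS = ("sample_id", "lipid_class", "species_id", "abundance")


def load_lipids(path) -> pd.DataFrame:
    """Read a lipid abundance TSV (``sample_id  lipid_class  species_id
    abundance``; abundances are extracted-ion-chromatogram AUC values,
    non-negative; lipid_class restricted to PC and DGTS)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"sample_id": str, "lipid_class": str,
                                "species_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty lipid table") from exc
    missing = [c for c in LIPID_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_class = ~df["lipid_class"].isin(LIPID_CLASSES)
    if bad_class.any():
        raise FormatError(
            f"{path}: lipid_class must be one of {LIPID_CLASSES}; got "
            f"{sorted(df.loc[bad_class, 'lipid_class'].unique())}")
    abundance = pd.to_numeric(df["abundance"], errors="coerce")
    if abundance.isna().any() or (abundance < 0).any():
        raise FormatError(f"{path}: abundances must be non-negative reals")
    df = df[list(LIPID_COLUMNS)].copy()
    df["abundance"] = abundance.astype(float)
    return df


def _class_total(table: pd.DataFrame, sample_id: str, lipid_class: str) -> float:
    rows = table[(table["sample_id"] == sample_id)
                 & (table["lipid_class"] == lipid_class)]
    return float(rows["abundance"].sum())


def dgts_pc_ratio(table: pd.DataFrame, sample_id: str) -> float:
    """DGTS/PC ratio for one sample: total DGTS AUC over total PC AUC.

    Returns NaN (the "undefined" flag) when the PC total is zero — both for
    DGTS > 0 (ratio unbounded) and for the degenerate 0/0 case. A sample with
    PC but no DGTS rows has ratio 0.0.
    """
    if sample_id not in set(table["sample_id"]):
        raise FormatError(f"unknown sample: {sample_id}")
    dgts = _class_total(table, sample_id, "DGTS")
    pc = _class_total(table, sample_id, "PC")
    if pc == 0.0:
        return math.nan
    return dgts / pc


def ratio_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample totals and DGTS/PC ratios for every sample in the table.
    Columns: ``sample_id, dgts_total, pc_total, ratio, defined``."""
    rows = []
    for sample in sorted(table["sample_id"].unique()):
        dgts = _class_total(table, sample, "DGTS")
        pc = _class_total(table, sample, "PC")
        ratio = dgts / pc if pc > 0 else math.nan
        rows.append((sample, dgts, pc, ratio, pc > 0))
    return pd.DataFrame(rows, columns=["sample_id", "dgts_total", "pc_total",
                                       "ratio", "defined"])


@dataclass(frozen=True)
class MarkerValidation:
    """2x2 association between a sequence marker and detectable lipid:
    counts over samples with both data types, exact two-sided p, and the
    per-sample ratio table for inspection."""

    marker_hmm: str
    n_marker_lipid: int      # marker+, lipid+
    n_marker_only: int       # marker+, lipid-
    n_lipid_only: int        # marker-, lipid+
    n_neither: int           # marker-, lipid-
    p_value: float
    log10_p: float
    ratios: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return (self.n_marker_lipid + self.n_marker_only
                + self.n_lipid_only + self.n_neither)


def validate_marker(presence: pd.Series, table: pd.DataFrame,
                    detect_threshold: float = 0.0,
                    marker_hmm: str | None = None) -> MarkerValidation:
    """Test whether marker-positive transcriptomes are the ones with
    detectable DGTS.

    ``presence`` is one PresenceMatrix column (0/1 indexed by sample_id);
    a sample is lipid-positive when its total DGTS AUC is strictly greater
    than ``detect_threshold`` (default 0: any nonzero AUC counts as
    detected). Samples present in only one of the two data sources are
    dropped with a warning; an empty intersection is an error.
    """
    if detect_threshold < 0:
        raise ParameterError("detect_threshold must be >= 0")
    if isinstance(presence, PresenceMatrix):
        raise ParameterError("pass a single matrix column (e.g. "
                             "matrix.column(hmm)), not the whole matrix")
    marker_hmm = marker_hmm or str(presence.name or "marker")
    ratios = ratio_table(table)
    lipid_samples = set(ratios["sample_id"])
    marker_samples = set(presence.index)
    shared = sorted(lipid_samples & marker_samples)
    if not shared:
        raise FormatError("no samples shared between presence calls and "
                          "lipid table")
    dropped = sorted(lipid_samples ^ marker_samples)
    if dropped:
        log.warning("dropping %d sample(s) present in only one data source: %s",
                    len(dropped), dropped)
    dgts_total = dict(zip(ratios["sample_id"], ratios["dgts_total"]))
    counts = [0, 0, 0, 0]  # both, marker_only, lipid_only, neither
    for sample in shared:
        marker_pos = bool(presence[sample])
        lipid_pos = dgts_total[sample] > detect_threshold
        idx = (0 if lipid_pos else 1) if marker_pos else (2 if lipid_pos else 3)
        counts[idx] += 1
    res = concordance_from_counts(counts[0], counts[3], counts[1], counts[2])
    shared_ratios = ratios[ratios["sample_id"].isin(shared)].reset_index(drop=True)
    return MarkerValidation(marker_hmm, counts[0], counts[1], counts[2],
                            counts[3], res.p_value, res.log10_p, shared_ratios)
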