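"""Profile-HMM hit tables and binary presence/absence calling.

A "hit" is one match of a profile HMM to one transcript of one sample's
assembled transcriptome, carrying the match bitscore (log2 likelihood-ratio
score). Presence of a gene family in a sample is called when at least one
transcript scores strictly above a bitscore threshold (default 10 bits); for
families embedded in large sequence superfamilies a dual-HMM score-ratio rule
is available that additionally requires the target-family score to exceed a
multiple of the score against a broader reference HMM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParameterError

REQUIRED_HIT_COLUMNS = ("sample_id", "hmm_id", "transcript_id", "bitscore")

#: Default presence-calling cutoff, in bits. A match must score *strictly*
#: above this value to count ("above" is read as a strict inequality).
DEFAULT_THRESHOLD = 10.0

#: Default factor for the dual-HMM ratio rule: the target-family bitscore
#: must be at least this many times the reference-HMM bitscore.
DEFAULT_RATIO_FACTOR = 5.0


def _data_line_numbers(path) -> list[int]:
    """File line numbers (1-based) of the data rows of a TSV, skipping
    '#'-comment lines, blank lines and the header row."""
    numbers = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            numbers.append(lineno)
    return numbers


def load_hits(path) -> pd.DataFrame:
    """Read a TSV of HMM hits into a DataFrame of hit records.

    The file must have a header naming the columns ``sample_id``, ``hmm_id``,
    ``transcript_id`` and ``bitscore`` (tab-separated, UTF-8, '.' decimal
    separator). Lines starting with '#' are ignored. Duplicate
    (sample, hmm, transcript) rows are allowed — HMM searches routinely emit
    several domain matches per transcript.

    Raises
    ------
    FormatError
        If a required column is missing, or a bitscore cannot be parsed as a
        finite real number (the message names the offending file line).
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"sample_id": str, "hmm_id": str, "transcript_id": str},
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row naming "
                          f"{REQUIRED_HIT_COLUMNS}") from exc
    missing = [c for c in REQUIRED_HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    raw = df["bitscore"]
    scores = pd.to_numeric(raw, errors="coerce")
    bad = scores.isna() | ~scores.apply(math.isfinite).astype(bool)
    if bad.any():
        lines = _data_line_numbers(path)
        first = bad.idxmax()
        lineno = lines[first] if first < len(lines) else "?"
        raise FormatError(
            f"{path}: unparseable or non-finite bitscore {raw[first]!r} at line {lineno}"
        )
    df = df[list(REQUIRED_HIT_COLUMNS)].copy()
    df["bitscore"] = scores.astype(float)
    return df


@dataclass(frozen=True)
class CladeMap:
    """Assignment of samples to named groups (e.g. the five major algal
    clades, or terminal clusters from a tree simplification)."""

    mapping: Mapping[str, str]
    order: tuple[str, ...]

    def __post_init__(self):
        if not self.mapping:
            raise FormatError("clade map is empty")
        unknown = set(self.order) ^ set(self.mapping.values())
        if unknown:
            raise FormatError(f"clade order does not match labels: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str],
                     order: Sequence[str] | None = None) -> "CladeMap":
        if order is None:
            seen: dict[str, None] = {}
            for label in mapping.values():
                seen.setdefault(label, None)
            order = tuple(seen)
        return cls(dict(mapping), tuple(order))

    @classmethod
    def from_tsv(cls, path) -> "CladeMap":
        """Read a two-column TSV with header ``sample_id<TAB>clade``."""
        try:
            df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty clade map") from exc
        for col in ("sample_id", "clade"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column(s): {col}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"{path}: samples assigned more than once: {dups}")
        return cls.from_mapping(dict(zip(df["sample_id"], df["clade"])))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def sizes(self, samples: Iterable[str] | None = None) -> dict[str, int]:
        """Number of samples per clade, optionally restricted to a subset."""
        pool = self.mapping if samples is None else {
            s: self.mapping[s] for s in samples
        }
        counts = {label: 0 for label in self.order}
        for label in pool.values():
            counts[label] += 1
        return counts

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tclade\n")
            for sample, label in self.mapping.items():
                fh.write(f"{sample}\t{label}\n")


@dataclass(eq=False)
class PresenceMatrix:
    """Binary samples x HMMs matrix plus provenance of the calling rule.

    ``calls`` is a pandas DataFrame indexed by sample_id with one 0/1 column
    per HMM; ``rule`` records how the calls were made (threshold and/or
    ratio parameters) so downstream reports can state their provenance.
    """

    calls: pd.DataFrame
    rule: dict = field(default_factory=dict)

    def __post_init__(self):
        values = self.calls.to_numpy()
        if values.size and not ((values == 0) | (values == 1)).all():
            raise FormatError("presence matrix entries must be 0 or 1")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise FormatError("duplicate sample or HMM identifiers in matrix")
        self.calls = self.calls.astype("int8")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def hmms(self) -> list[str]:
        return list(self.calls.columns)

    def column(self, hmm_id: str) -> pd.Series:
        if hmm_id not in self.calls.columns:
            raise FormatError(f"unknown HMM id: {hmm_id}")
        return self.calls[hmm_id]

    def restrict(self, samples: Sequence[str]) -> "PresenceMatrix":
        missing = [s for s in samples if s not in self.calls.index]
        if missing:
            raise FormatError(f"samples absent from matrix: {missing}")
        return PresenceMatrix(self.calls.loc[list(samples)], dict(self.rule))

    def equals(self, other: "PresenceMatrix") -> bool:
        return self.calls.equals(other.calls)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.calls.to_csv(fh, sep="\t", index_label="sample_id",
                              lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, rule: dict | None = None) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
        df.index = df.index.astype(str)
        return cls(df, rule or {"kind": "loaded", "path": str(path)})


def presence_call(hits: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                  samples: Sequence[str] | None = None,
                  hmms: Sequence[str] | None = None) -> PresenceMatrix:
    """Call presence/absence from hit records: sample s is positive for HMM h
    iff at least one of its transcripts matches h with bitscore strictly
    greater than ``threshold``.

    ``samples``/``hmms`` fix the row/column universe (and order); samples or
    HMMs with no hits at all become all-zero rows/columns — non-detection is
    treated as absence. Without an explicit universe, rows and columns are the
    sorted identifiers seen in ``hits``.
    """
    if not math.isfinite(threshold):
        raise ParameterError(f"threshold must be finite, got {threshold!r}")
    if samples is None:
        samples = sorted(hits["sample_id"].unique()) if len(hits) else []
    if hmms is None:
        hmms = sorted(hits["hmm_id"].unique()) if len(hits) else []
    positive = hits[hits["bitscore"] > threshold]
    if len(positive):
        table = (
            positive.groupby(["sample_id", "hmm_id"], sort=False)
            .size()
            .clip(upper=1)
            .unstack(fill_value=0)
        )
    else:
        table = pd.DataFrame(index=pd.Index([], dtype=str),
                             columns=pd.Index([], dtype=str), dtype="int8")
    table = table.reindex(index=list(samples), columns=list(hmms), fill_value=0)
    return PresenceMatrix(table, {"kind": "threshold", "threshold": threshold})


def ratio_call(hits: pd.DataFrame, target_hmm: str, reference_hmm: str,
               factor: float = DEFAULT_RATIO_FACTOR,
               floor: float = DEFAULT_THRESHOLD,
               samples: Sequence[str] | None = None) -> pd.Series:
    """Dual-HMM annotation: presence calls for ``target_hmm`` requiring, per
    transcript, a target bitscore b_T strictly above ``floor`` AND
    b_T >= factor * b_R, where b_R is that transcript's best bitscore against
    ``reference_hmm`` (imputed as ``floor`` when the transcript has no
    reference hit, so that absent reference evidence cannot disqualify a
    strong target hit).

    This is the calling rule used to separate a specific family (e.g. a
    CbbX-type Rubisco activase) from a sprawling superfamily (the AAA+
    ATPases) that the single-HMM threshold cannot resolve. Returns an int8
    Series of 0/1 indexed by sample_id.
    """
    if not factor > 0:
        raise ParameterError(f"ratio factor must be positive, got {factor!r}")
    if samples is None:
        samples = sorted(hits["sample_id"].unique()) if len(hits) else []
    key = ["sample_id", "transcript_id"]
    target = (hits[hits["hmm_id"] == target_hmm]
              .groupby(key)["bitscore"].max())
    reference = (hits[hits["hmm_id"] == reference_hmm]
                 .groupby(key)["bitscore"].max())
    ref_aligned = reference.reindex(target.index).fillna(floor)
    qualifies = (target > floor) & (target >= factor * ref_aligned)
    positive_samples = set(
        target.index.get_level_values("sample_id")[qualifies.to_numpy()]
    )
    out = pd.Series(
        [1 if s in positive_samples else 0 for s in samples],
        index=pd.Index(list(samples), name="sample_id"),
        dtype="int8",
        name=target_hmm,
    )
    return out


def clade_fractions(matrix: PresenceMatrix, clades: CladeMap) -> pd.DataFrame:
    """Per-HMM, per-clade positive counts and fractions.

    Returns a tidy DataFrame with columns ``hmm_id, clade, positives, size,
    fraction``, ordered by HMM then by the clade map's reporting order. Clades
    with no samples in the matrix are omitted. Every matrix sample must be
    labeled.
    """
    unlabeled = [s for s in matrix.samples if s not in clades.mapping]
    if unlabeled:
        raise FormatError(f"samples missing from clade map: {unlabeled}")
    if not matrix.samples or not matrix.hmms:
        return pd.DataFrame(
            columns=["hmm_id", "clade", "positives", "size", "fraction"]
        )
    labels = pd.Series({s: clades.mapping[s] for s in matrix.samples})
    sizes = labels.value_counts()
    positives = matrix.calls.groupby(labels).sum()
    rows = []
    for hmm in matrix.hmms:
        for clade in clades.order:
            if clade not in sizes.index:
                continue
            k = int(positives.loc[clade, hmm]) if clade in positives.index else 0
            n = int(sizes[clade])
            rows.append((hmm, clade, k, n, k / n))
    return pd.DataFrame(rows, columns=["hmm_id", "clade", "positives", "size",
                                       "fraction"])
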