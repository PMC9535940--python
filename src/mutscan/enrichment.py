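"""Per-variant frequency computation and the three-filter enrichment pipeline.

The substrate is a :class:`VariantCountTable`: per-variant read counts plus
per-position coverage across named library conditions (the unselected input,
one or more activation-selected libraries, one or more loss-of-function
reference libraries).  The pipeline keeps variants that

1. exceed a frequency threshold (strict ``>``) in at least one
   activation-selected condition,
2. are enriched more than a fold threshold (strict ``>``) over the
   loss-of-function reference frequency (max over references; zero reference
   frequencies are replaced by a pseudofrequency of ``0.5 / coverage``), and
3. appear in a catalogue of cancer-listed protein substitutions.

The final verdict is the AND of the three flags, so filter order is
irrelevant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

KEY_COLS = ["nt_pos", "ref", "alt", "protein_change"]

_LABEL_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")


class DataIntegrityError(ValueError):
    """Raised when a count table violates its own invariants."""


def normalize_protein_change(label: str) -> str:
    """Normalize a protein-substitution label to ``X123Y`` form.

    Raises ``ValueError`` for labels that cannot be normalized (callers that
    must be lenient catch this and log an exclusion).
    """
    norm = str(label).strip().upper().replace("P.", "")
    if not _LABEL_RE.match(norm):
        raise ValueError(f"unnormalizable protein-change label: {label!r}")
    return norm


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass
class VariantCountTable:
    """Per-variant read counts and per-position coverage per condition.

    ``data`` holds one row per variant with the key columns
    ``nt_pos, ref, alt, protein_change`` plus, for every condition ``c``,
    an integer column ``count_<c>`` and a positive integer column
    ``cov_<c>`` (coverage at that variant's nucleotide position).
    """

    data: pd.DataFrame
    conditions: list[str]

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    def counts(self, condition: str) -> pd.Series:
        self._check_condition(condition)
        return self.data[f"count_{condition}"]

    def coverage(self, condition: str) -> pd.Series:
        self._check_condition(condition)
        return self.data[f"cov_{condition}"]

    def _check_condition(self, condition: str) -> None:
        if condition not in self.conditions:
            raise KeyError(
                f"unknown condition {condition!r}; have {self.conditions}"
            )

    def __len__(self) -> int:
        return len(self.data)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise DataIntegrityError("condition names must be unique")
        for col in KEY_COLS:
            if col not in self.data.columns:
                raise DataIntegrityError(f"missing key column {col!r}")
        for c in self.conditions:
            cnt, cov = self.data[f"count_{c}"], self.data[f"cov_{c}"]
            if (cnt < 0).any():
                raise DataIntegrityError(f"negative counts in condition {c!r}")
            bad = (cov <= 0) & (cnt > 0)
            if bad.any():
                raise DataIntegrityError(
                    f"count > 0 at zero coverage in condition {c!r}"
                )
            if (cnt > cov).any():
                raise DataIntegrityError(
                    f"variant count exceeds coverage in condition {c!r}"
                )

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantCountTable":
        df = pd.read_csv(path, sep="\t")
        conditions = [
            c[len("count_"):] for c in df.columns if c.startswith("count_")
        ]
        return cls(df, conditions)


@dataclass
class FrequencyTable:
    """Per-variant frequencies ``f = count / coverage`` per condition.

    Coverage columns are retained so that downstream pseudofrequency
    handling (zero reference frequency) can use ``0.5 / coverage``.
    """

    data: pd.DataFrame
    conditions: list[str]

    def frequencies(self, condition: str) -> pd.Series:
        if condition not in self.conditions:
            raise KeyError(
                f"unknown condition {condition!r}; have {self.conditions}"
            )
        return self.data[f"freq_{condition}"]

    def coverage(self, condition: str) -> pd.Series:
        return self.data[f"cov_{condition}"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CosmicFixture:
    """Catalogue of protein-level substitutions with occurrence counts."""

    data: pd.DataFrame  # columns: protein_change, occurrence_count

    def __post_init__(self) -> None:
        if (self.data["occurrence_count"] < 1).any():
            raise DataIntegrityError("occurrence_count must be >= 1")
        self.data = self.data.assign(
            protein_change=self.data["protein_change"].map(
                normalize_protein_change
            )
        )

    def __contains__(self, label: str) -> bool:
        try:
            norm = normalize_protein_change(label)
        except ValueError:
            return False
        return norm in set(self.data["protein_change"])

    def labels(self) -> set[str]:
        return set(self.data["protein_change"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CosmicFixture":
        return cls(pd.read_csv(path, sep="\t"))


def load_packaged_cosmic() -> CosmicFixture:
    """Load the packaged mini-catalogue used by the worked example."""
    with resources.as_file(
        resources.files("mutscan.data") / "cosmic_mini.tsv"
    ) as p:
        return CosmicFixture.from_tsv(p)


def load_packaged_counts() -> VariantCountTable:
    """Load the packaged demonstration count table (worked example)."""
    with resources.as_file(
        resources.files("mutscan.data") / "demo_counts.tsv"
    ) as p:
        return VariantCountTable.from_tsv(p)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_frequencies(table: VariantCountTable) -> FrequencyTable:
    """Exact per-condition frequencies ``count / coverage`` (no smoothing)."""
    df = table.data[KEY_COLS].copy()
    for c in table.conditions:
        cnt = table.counts(c).to_numpy(dtype=float)
        cov = table.coverage(c).to_numpy(dtype=float)
        if ((cov <= 0) & (cnt > 0)).any():
            raise DataIntegrityError(
                f"count > 0 at zero coverage in condition {c!r}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(cov > 0, cnt / cov, 0.0)
        df[f"freq_{c}"] = f
        df[f"cov_{c}"] = table.coverage(c).to_numpy()
    return FrequencyTable(df, list(table.conditions))


def _row_keys(df: pd.DataFrame) -> list[tuple]:
    return list(zip(df["nt_pos"], df["ref"], df["alt"]))


def filter_frequency(
    freqs: FrequencyTable,
    conditions: list[str],
    threshold: float = 0.01,
) -> set[tuple]:
    """Filter 1: frequency strictly above ``threshold`` in >=1 condition."""
    if not conditions:
        raise ValueError("need at least one activation-selected condition")
    mask = np.zeros(len(freqs), dtype=bool)
    for c in conditions:
        mask |= freqs.frequencies(c).to_numpy() > threshold
    keys = _row_keys(freqs.data)
    return {k for k, m in zip(keys, mask) if m}


def reference_frequency(
    freqs: FrequencyTable, reference_conditions: list[str]
) -> np.ndarray:
    """Max reference frequency, with zero replaced by ``0.5 / coverage``."""
    if not reference_conditions:
        raise ValueError("need at least one reference condition")
    cols = []
    for c in reference_conditions:
        f = freqs.frequencies(c).to_numpy(dtype=float)
        cov = freqs.coverage(c).to_numpy(dtype=float)
        cols.append(np.where(f > 0, f, 0.5 / cov))
    return np.max(np.vstack(cols), axis=0)


def filter_fold_enrichment(
    freqs: FrequencyTable,
    activation_condition: str,
    reference_condition: str | list[str],
    fold: float = 8.0,
) -> set[tuple]:
    """Filter 2: strictly more than ``fold`` enriched over the reference."""
    refs = (
        [reference_condition]
        if isinstance(reference_condition, str)
        else list(reference_condition)
    )
    f_act = freqs.frequencies(activation_condition).to_numpy(dtype=float)
    f_ref = reference_frequency(freqs, refs)
    mask = f_act / f_ref > fold
    keys = _row_keys(freqs.data)
    return {k for k, m in zip(keys, mask) if m}


def filter_cosmic(
    protein_changes, cosmic: CosmicFixture
) -> set[str]:
    """Filter 3: membership of the protein-change label in the catalogue.

    Synonymous labels (e.g. ``L927L``) participate like any other; the
    filter is membership only.  Unnormalizable labels are excluded with a
    warning.
    """
    kept: set[str] = set()
    for label in protein_changes:
        try:
            norm = normalize_protein_change(label)
        except ValueError as exc:
            warnings.warn(f"excluding variant: {exc}", stacklevel=2)
            continue
        if norm in cosmic:
            kept.add(norm)
    return kept


@dataclass
class FilterConfig:
    activation_conditions: list[str]
    reference_conditions: list[str]
    freq_threshold: float = 0.01
    fold_threshold: float = 8.0


@dataclass
class FilterReport:
    """Per-variant filter flags, per-experiment provenance and survivors."""

    data: pd.DataFrame
    config: FilterConfig

    @property
    def survivors(self) -> list[str]:
        """Protein-change labels passing all three filters (table order)."""
        return self.data.loc[self.data["verdict"], "protein_change"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n = len(self.data)
        lines = [
            f"{n} variants; "
            f"filter1 (freq > {self.config.freq_threshold}): "
            f"{int(self.data['pass_filter1'].sum())} pass; "
            f"filter2 (fold > {self.config.fold_threshold}): "
            f"{int(self.data['pass_filter2'].sum())} pass; "
            f"filter3 (catalogue): "
            f"{int(self.data['pass_filter3'].sum())} pass",
            "survivors: " + (", ".join(self.survivors) or "(none)"),
        ]
        return "\n".join(lines)


def run_filter_pipeline(
    table: VariantCountTable,
    cosmic: CosmicFixture,
    config: FilterConfig,
) -> FilterReport:
    """Apply the three filters and report per-variant flags and provenance.

    The final verdict is the AND of the three per-filter flags, each of
    which ORs over the listed activation-selected experiments, so the
    report is independent of filter application order.
    """
    if not config.activation_conditions:
        raise ValueError("at least one activation condition required")
    if not config.reference_conditions:
        raise ValueError("at least one reference condition required")
    freqs = compute_frequencies(table)
    out = freqs.data[KEY_COLS].copy()

    pass1 = np.zeros(len(out), dtype=bool)
    pass2 = np.zeros(len(out), dtype=bool)
    f_ref = reference_frequency(freqs, config.reference_conditions)
    out["freq_reference"] = np.max(
        np.vstack(
            [
                freqs.frequencies(c).to_numpy()
                for c in config.reference_conditions
            ]
        ),
        axis=0,
    )
    for c in config.activation_conditions:
        f_act = freqs.frequencies(c).to_numpy(dtype=float)
        hit1 = f_act > config.freq_threshold
        hit2 = f_act / f_ref > config.fold_threshold
        out[f"freq_{c}"] = f_act
        out[f"fold_{c}"] = f_act / f_ref
        out[f"hit_filter1_{c}"] = hit1
        out[f"hit_filter2_{c}"] = hit2
        pass1 |= hit1
        pass2 |= hit2

    pass3 = np.zeros(len(out), dtype=bool)
    cosmic_labels = cosmic.labels()
    for i, label in enumerate(out["protein_change"]):
        try:
            pass3[i] = normalize_protein_change(label) in cosmic_labels
        except ValueError as exc:
            warnings.warn(f"excluding variant: {exc}", stacklevel=2)
            pass3[i] = False

    out["pass_filter1"] = pass1
    out["pass_filter2"] = pass2
    out["pass_filter3"] = pass3
    out["verdict"] = pass1 & pass2 & pass3
    return FilterReport(out, config)


# ---------------------------------------------------------------------------
# coverage QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    valid: bool
    per_condition: pd.DataFrame = field(default_factory=pd.DataFrame)
    failing_positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.valid
            and bool(self.per_condition["pass"].all())
            and not any(self.failing_positions.values())
        )


def coverage_qc(
    table: VariantCountTable,
    mean_min: int = 100_000,
    per_position_min: int = 40_000,
) -> QCReport:
    """Flag conditions with low mean or low per-position coverage."""
    if len(table) == 0:
        return QCReport(valid=False)
    rows = []
    failing: dict[str, list[int]] = {}
    per_pos = table.data.groupby("nt_pos")
    for c in table.conditions:
        pos_cov = per_pos[f"cov_{c}"].first()
        mean_cov = float(pos_cov.mean())
        low = pos_cov.index[pos_cov < per_position_min].tolist()
        failing[c] = low
        rows.append(
            {
                "condition": c,
                "mean_coverage": mean_cov,
                "min_coverage": int(pos_cov.min()),
                "n_positions_below_min": len(low),
                "pass": mean_cov >= mean_min and not low,
            }
        )
    return QCReport(
        valid=True,
        per_condition=pd.DataFrame(rows),
        failing_positions=failing,
    )
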