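"""Kyte-Doolittle hydropathy profiles, transmembrane candidate scanning and
small-x-x-x-small dimerization-motif detection.

The candidate scan keeps catalogue-listed substitutions whose mutant residue
is hydrophilic (KD < 0 by default) and which sit strictly more than
``margin`` residues from either end of the annotated transmembrane span —
residues near the membrane surface can snorkel toward the head groups and
are therefore excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CosmicFixture, normalize_protein_change

#: Kyte & Doolittle hydropathy index, one value per standard residue.
KD_SCALE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Residues counted as "small" in dimerization motifs (configurable).
DEFAULT_SMALL_SET = frozenset("GAST")


def kd_value(residue: str) -> float:
    try:
        return KD_SCALE[residue.upper()]
    except KeyError:
        raise ValueError(f"unknown residue letter {residue!r}") from None


def kd_profile(
    sequence: str,
    numbering_offset: int = 1,
    window: int | None = None,
) -> pd.DataFrame:
    """Per-residue KD values with an optional centered sliding-window mean.

    The window mean is undefined (NaN) within ``window // 2`` residues of
    either end.  ``window`` must be odd.
    """
    seq = sequence.upper()
    values = np.array([kd_value(r) for r in seq])
    df = pd.DataFrame(
        {
            "position": np.arange(len(seq)) + numbering_offset,
            "residue": list(seq),
            "kd": values,
        }
    )
    if window is not None:
        if window < 1 or window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        df["kd_window_mean"] = (
            pd.Series(values).rolling(window, center=True).mean().to_numpy()
        )
    return df


def classify_hydrophilic(residue: str, threshold: float = 0.0) -> bool:
    """True iff the residue's KD value is strictly below ``threshold``."""
    return kd_value(residue) < threshold


@dataclass(frozen=True)
class TMAnnotation:
    """Inclusive transmembrane span with a minimum distance from its ends."""

    tm_start: int
    tm_end: int
    margin: int = 5

    def __post_init__(self) -> None:
        if not self.tm_start < self.tm_end:
            raise ValueError("tm_start must be < tm_end")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.tm_end - self.tm_start + 1 <= 2 * self.margin:
            raise ValueError("span too short for the requested margin")

    def is_central(self, position: int) -> bool:
        """Strictly more than ``margin`` residues from either end."""
        return (
            position - self.tm_start > self.margin
            and self.tm_end - position > self.margin
        )


def parse_substitution(label: str) -> tuple[str, int, str]:
    """Split ``L658Q`` into ``('L', 658, 'Q')``."""
    norm = normalize_protein_change(label)
    return norm[0], int(norm[1:-1]), norm[-1]


def scan_tm_candidates(
    mutations: CosmicFixture | pd.DataFrame,
    tm: TMAnnotation,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Nominate hydrophilic, membrane-central catalogue substitutions.

    Returns one row per candidate with the wild-type and mutant KD values.
    Synonymous or unparsable labels, and positions outside the annotated
    span, are skipped with a warning.
    """
    df = mutations.data if isinstance(mutations, CosmicFixture) else mutations
    rows = []
    for rec in df.itertuples():
        label = rec.protein_change
        try:
            wt, pos, mut = parse_substitution(label)
            if "*" in (wt, mut):
                raise ValueError("nonsense change")
            wt_kd, mut_kd = kd_value(wt), kd_value(mut)
        except ValueError as exc:
            warnings.warn(f"skipping {label!r}: {exc}", stacklevel=2)
            continue
        if wt == mut:
            continue
        if not (tm.tm_start <= pos <= tm.tm_end):
            continue
        if not tm.is_central(pos):
            continue
        if not mut_kd < threshold:
            continue
        rows.append(
            {
                "protein_change": label,
                "position": pos,
                "wt_residue": wt,
                "mut_residue": mut,
                "wt_kd": wt_kd,
                "mut_kd": mut_kd,
                "occurrence_count": getattr(rec, "occurrence_count", np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_change", "position", "wt_residue", "mut_residue",
            "wt_kd", "mut_kd", "occurrence_count",
        ],
    ).sort_values("position", ignore_index=True)


# ---------------------------------------------------------------------------
# dimerization motifs
# ---------------------------------------------------------------------------

SINGLE_PATTERN = "small-x-x-x-small"
DOUBLE_PATTERN = "small-small-x-x-small-small"


@dataclass(frozen=True)
class MotifHit:
    """A dimerization-motif match at ``start`` (in sequence numbering)."""

    start: int
    pattern: str
    subsequence: str


def find_small_x_motifs(
    sequence: str,
    small_set: frozenset[str] | set[str] = DEFAULT_SMALL_SET,
    numbering_offset: int = 1,
) -> list[MotifHit]:
    """All small-x-x-x-small motifs, plus overlapping double motifs.

    Two single hits offset by one residue are additionally reported as a
    small-small-x-x-small-small double motif spanning six residues.
    """
    seq = sequence.upper()
    small = {s.upper() for s in small_set}
    singles = [
        i
        for i in range(len(seq) - 4)
        if seq[i] in small and seq[i + 4] in small
    ]
    hits = [
        MotifHit(i + numbering_offset, SINGLE_PATTERN, seq[i:i + 5])
        for i in singles
    ]
    single_set = set(singles)
    hits.extend(
        MotifHit(i + numbering_offset, DOUBLE_PATTERN, seq[i:i + 6])
        for i in singles
        if i + 1 in single_set
    )
    return sorted(hits, key=lambda h: (h.start, h.pattern))


def load_packaged_tm_mutations() -> CosmicFixture:
    """Packaged catalogue subset for the transmembrane neighborhood scan."""
    with resources.as_file(
        resources.files("mutscan.data") / "tm_cosmic_mutations.tsv"
    ) as p:
        return CosmicFixture.from_tsv(p)


def load_packaged_tm_segment() -> tuple[str, int]:
    """Packaged transmembrane-neighborhood sequence and numbering offset."""
    from Bio import SeqIO

    with resources.as_file(
        resources.files("mutscan.data") / "tm_segment.fa"
    ) as p:
        rec = next(SeqIO.parse(str(p), "fasta"))
    offset = 1
    for token in rec.description.split():
        if token.startswith("offset="):
            offset = int(token.split("=", 1)[1])
    return str(rec.seq), offset


def write_profile_tsv(
    profile: pd.DataFrame, path: str | Path
) -> None:
    profile.to_csv(path, sep="\t", index=False)
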