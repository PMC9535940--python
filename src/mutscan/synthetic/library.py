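"""Single-nucleotide-variant library enumeration and selection simulation.

The library model mirrors an error-prone-PCR library of single-nucleotide
clones: every clone carries exactly one substitution, reads span the whole
amplicon (so per-position coverage equals sequencing depth), and selection
multiplies each clone's abundance by ``activity ** s`` per round with
``s = -ln(gate_stringency)``.  PCR artifacts are modelled after sequencing
as base-call errors on the wild-type read pool, with the C->T rate boosted
by a configurable bias factor; artifact reads displace wild-type reads so
coverage is conserved.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from ..enrichment import KEY_COLS, VariantCountTable

_BASES = "ACGT"
_STOP = set(standard_dna_table.stop_codons)
_SENSE_CODONS = sorted(
    c
    for c in ("".join(b) for b in itertools.product(_BASES, repeat=3))
    if c not in _STOP
)


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence with a residue-numbering offset.

    ``numbering_offset`` is the residue number of the first codon (default 1),
    so library variants can be labelled in precursor numbering.
    """

    id: str
    nucleotides: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if set(nt) - set(_BASES):
            raise ValueError(
                f"non-ACGT characters in CDS: {sorted(set(nt) - set(_BASES))}"
            )
        if len(nt) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        protein = str(Seq(nt).translate())
        if "*" in protein[:-1]:
            raise ValueError("CDS contains an internal stop codon")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, codon_index: int) -> str:
        """Codon at 0-based ``codon_index``."""
        return self.nucleotides[3 * codon_index: 3 * codon_index + 3]

    def residue_number(self, codon_index: int) -> int:
        return self.numbering_offset + codon_index


def random_cds(
    n_codons: int, seed: int, id: str = "synthetic_cds",
    numbering_offset: int = 1,
) -> CodingSequence:
    """Random CDS of ``n_codons`` sense codons (no internal stops)."""
    rng = np.random.default_rng(seed)
    codons = rng.choice(_SENSE_CODONS, size=n_codons)
    return CodingSequence(id, "".join(codons), numbering_offset)


@dataclass(frozen=True)
class VariantSpec:
    """One single-nucleotide variant with its ground-truth activity."""

    nt_position: int  # 1-based
    ref_base: str
    alt_base: str
    protein_change: str
    true_activity: float = 1.0

    @property
    def synonymous(self) -> bool:
        return (
            self.protein_change[0] == self.protein_change[-1]
            and self.protein_change[0] != "*"
        )


def protein_change_label(cds: CodingSequence, nt_position: int, alt: str) -> str:
    """Protein-level label of a substitution (synonymous as e.g. ``L927L``)."""
    i = nt_position - 1
    ci, off = divmod(i, 3)
    codon = cds.codon(ci)
    mut_codon = codon[:off] + alt + codon[off + 1:]
    wt_aa = str(Seq(codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    return f"{wt_aa}{cds.residue_number(ci)}{mut_aa}"


def enumerate_snv_library(cds: CodingSequence) -> list[VariantSpec]:
    """All ``3 * len(cds)`` single-nucleotide variants of the CDS."""
    variants = []
    for i, ref in enumerate(cds.nucleotides):
        for alt in _BASES:
            if alt == ref:
                continue
            variants.append(
                VariantSpec(
                    nt_position=i + 1,
                    ref_base=ref,
                    alt_base=alt,
                    protein_change=protein_change_label(cds, i + 1, alt),
                )
            )
    return variants


def assign_activities(
    variants: list[VariantSpec],
    activating_map: dict[str, float],
) -> list[VariantSpec]:
    """Assign ground-truth activities by protein-change label.

    Mapped variants receive the mapped activity; everything else (including
    all synonymous variants) stays at wild-type activity 1.0.  Keys that no
    single-nucleotide change can produce trigger a warning and are skipped.
    """
    for label, activity in activating_map.items():
        if activity < 0:
            raise ValueError(f"negative activity for {label!r}")
    producible = {v.protein_change for v in variants}
    skipped = sorted(set(activating_map) - producible)
    if skipped:
        warnings.warn(
            "activating-map keys not producible by any single-nucleotide "
            f"change, skipped: {skipped}",
            stacklevel=2,
        )
    out = []
    for v in variants:
        if v.synonymous:
            out.append(replace(v, true_activity=1.0))
        elif v.protein_change in activating_map:
            out.append(replace(v, true_activity=float(activating_map[v.protein_change])))
        else:
            out.append(replace(v, true_activity=1.0))
    return out


@dataclass
class SelectionConfig:
    """Parameters of the simulated selection / sequencing experiment."""

    rounds: int = 2
    gate_stringency: float = 0.05  # fraction of cells sorted per round
    depth_per_round: int = 1_000_000
    pcr_error_rate: float = 0.0  # per base per substitution type
    ct_bias_factor: float = 1.0  # multiplier on the C->T rate
    seed: int = 0
    wt_fraction: float = 0.1  # wild-type clones in the input library

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if not 0 < self.gate_stringency <= 1:
            raise ValueError("gate_stringency must be in (0, 1]")
        if self.depth_per_round <= 0:
            raise ValueError("depth_per_round must be > 0")
        if not 0 <= self.pcr_error_rate <= 1:
            raise ValueError("pcr_error_rate must be in [0, 1]")
        if self.ct_bias_factor < 1:
            raise ValueError("ct_bias_factor must be >= 1")
        if self.pcr_error_rate * self.ct_bias_factor > 1:
            raise ValueError("pcr_error_rate * ct_bias_factor exceeds 1")
        if not 0 <= self.wt_fraction < 1:
            raise ValueError("wt_fraction must be in [0, 1)")

    @property
    def selection_exponent(self) -> float:
        """Per-round enrichment exponent ``s = -ln(gate_stringency)``."""
        return -math.log(self.gate_stringency)


def _expected_abundances(
    variants: list[VariantSpec], config: SelectionConfig, rounds: int,
    invert: bool = False,
) -> np.ndarray:
    """Normalized clone abundances (variants + trailing wt) after ``rounds``."""
    n = len(variants)
    act = np.array([v.true_activity for v in variants], dtype=float)
    if invert:
        act = 1.0 / np.maximum(act, 1e-3)
    abund = np.empty(n + 1)
    abund[:n] = (1.0 - config.wt_fraction) / n
    abund[n] = config.wt_fraction
    if abund[:n].sum() <= 0 and abund[n] <= 0:
        raise ValueError("zero total abundance")
    factor = act ** config.selection_exponent
    for _ in range(rounds):
        abund[:n] *= factor
        total = abund.sum()
        if total <= 0:
            raise ValueError("zero total abundance after selection")
        abund /= total
    return abund / abund.sum()


def simulate_selection_counts(
    variants: list[VariantSpec],
    config: SelectionConfig,
    condition_names: list[str] | None = None,
    invert_selection: bool = False,
    seed_stream: int = 0,
) -> VariantCountTable:
    """Simulate per-round sequencing counts of a library under selection.

    Per round each clone's abundance is multiplied by
    ``activity ** s`` (``s = -ln(gate_stringency)``), abundances are
    renormalized, and counts are drawn by multinomial sampling at
    ``depth_per_round``.  The output has one condition per round plus the
    unselected ``input``.  ``invert_selection`` selects *against* activity
    (a loss-of-function reference selection).
    """
    if not variants:
        raise ValueError("empty variant list")
    if condition_names is None:
        condition_names = ["input"] + [
            f"round{r}" for r in range(1, config.rounds + 1)
        ]
    if len(condition_names) != config.rounds + 1:
        raise ValueError("need one condition name per round plus input")
    rng = np.random.default_rng([config.seed, seed_stream])
    n = len(variants)
    df = pd.DataFrame(
        {
            "nt_pos": [v.nt_position for v in variants],
            "ref": [v.ref_base for v in variants],
            "alt": [v.alt_base for v in variants],
            "protein_change": [v.protein_change for v in variants],
        }
    )
    for r, name in enumerate(condition_names):
        abund = _expected_abundances(variants, config, r, invert_selection)
        draw = rng.multinomial(config.depth_per_round, abund)
        df[f"count_{name}"] = draw[:n]
        df[f"cov_{name}"] = config.depth_per_round
    return VariantCountTable(df, condition_names)


def apply_pcr_noise(
    table: VariantCountTable,
    config: SelectionConfig,
    mirror_ga: bool = False,
    seed_stream: int = 1,
) -> VariantCountTable:
    """Add PCR-artifact counts, reassigned from the wild-type read pool.

    At every nucleotide position and condition, the reads still calling the
    reference base are redistributed multinomially: each alternative base
    receives probability ``pcr_error_rate``, multiplied by
    ``ct_bias_factor`` for C->T (and, when ``mirror_ga``, for G->A).
    Column sums (coverage) are conserved exactly.
    """
    if config.pcr_error_rate == 0:
        return VariantCountTable(table.data.copy(), list(table.conditions))
    rng = np.random.default_rng([config.seed, seed_stream])
    df = table.data.copy().reset_index(drop=True)
    for cond in table.conditions:
        ccol = f"count_{cond}"
        for _, idx in df.groupby("nt_pos").groups.items():
            rows = df.loc[idx]
            ref = rows["ref"].iloc[0]
            cov = int(rows[f"cov_{cond}"].iloc[0])
            wt_reads = cov - int(rows[ccol].sum())
            if wt_reads <= 0:
                continue
            probs = []
            for alt in rows["alt"]:
                p = config.pcr_error_rate
                if (ref == "C" and alt == "T") or (
                    mirror_ga and ref == "G" and alt == "A"
                ):
                    p *= config.ct_bias_factor
                probs.append(p)
            probs.append(1.0 - sum(probs))
            if probs[-1] < 0:
                raise ValueError("total artifact rate exceeds 1 at a position")
            draw = rng.multinomial(wt_reads, probs)
            df.loc[idx, ccol] = rows[ccol].to_numpy() + draw[:-1]
    return VariantCountTable(df, list(table.conditions))


def simulate_screen(
    variants: list[VariantSpec],
    config: SelectionConfig,
    n_activation_experiments: int = 2,
    mirror_ga: bool = False,
) -> VariantCountTable:
    """Simulate a full screen: activation selections plus a reference.

    Returns a table with conditions ``input``, one ``act<X>_r<rounds>``
    column per independent activation experiment (A, B, ...), and a
    loss-of-function reference ``lof_ref`` selected against activity.
    PCR-artifact noise is applied to every condition (the amplification
    step precedes sequencing in all of them), so artifacts accumulate
    independently of the selection pressure.
    """
    letters = "ABCDEFGH"
    tables = []
    final = f"r{config.rounds}"
    for k in range(n_activation_experiments):
        name = f"act{letters[k]}_{final}"
        t = simulate_selection_counts(
            variants,
            config,
            condition_names=["input"]
            + [f"_tmp{r}" for r in range(1, config.rounds)]
            + [name],
            seed_stream=10 + k,
        )
        tables.append((t, name, k == 0))
    lof = simulate_selection_counts(
        variants,
        config,
        condition_names=["_lin"]
        + [f"_ltmp{r}" for r in range(1, config.rounds)]
        + ["lof_ref"],
        invert_selection=True,
        seed_stream=50,
    )

    merged = tables[0][0].data[KEY_COLS].copy()
    conditions = ["input"]
    merged["count_input"] = tables[0][0].counts("input")
    merged["cov_input"] = tables[0][0].coverage("input")
    for t, name, _ in tables:
        merged[f"count_{name}"] = t.counts(name).to_numpy()
        merged[f"cov_{name}"] = t.coverage(name).to_numpy()
        conditions.append(name)
    merged["count_lof_ref"] = lof.counts("lof_ref").to_numpy()
    merged["cov_lof_ref"] = lof.coverage("lof_ref").to_numpy()
    conditions.append("lof_ref")

    out = VariantCountTable(merged, conditions)
    noisy = apply_pcr_noise(out, config, mirror_ga=mirror_ga, seed_stream=99)
    return noisy
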