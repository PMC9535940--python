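"""Nonequilibrium free-energy estimation and thermodynamic-cycle assembly.

Sign convention (documented prominently because it is a common source of
error): reverse work values ``W_r`` are stored as the work of the *reverse*
transformation.  The Crooks comparison negates them internally, i.e. the
intersection is computed between Gaussian fits of ``W_f`` and of ``-W_r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: kT at 310 K in kJ/mol (k_B * 310 K * N_A).
DEFAULT_KT = 2.577


class CrooksIntersectionError(ValueError):
    """No physically meaningful intersection between the fitted Gaussians."""

    def __init__(self, roots, mu_f, mu_r):
        self.roots = roots
        super().__init__(
            f"no real intersection between fitted means {mu_f:.4g} and "
            f"{mu_r:.4g}; roots: {roots}"
        )


@dataclass
class WorkSampleSet:
    """Forward / reverse work values (kJ/mol) with their temperature."""

    forward: np.ndarray
    reverse: np.ndarray = field(default_factory=lambda: np.empty(0))
    kT: float = DEFAULT_KT

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.forward.size < 1:
            raise ValueError("need at least one forward work value")

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "direction": ["forward"] * self.forward.size
                + ["reverse"] * self.reverse.size,
                "work_kJ_mol": np.concatenate([self.forward, self.reverse]),
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, kT: float = DEFAULT_KT) -> "WorkSampleSet":
        df = pd.read_csv(path, sep="\t")
        fwd = df.loc[df["direction"] == "forward", "work_kJ_mol"].to_numpy()
        rev = df.loc[df["direction"] == "reverse", "work_kJ_mol"].to_numpy()
        return cls(forward=fwd, reverse=rev, kT=kT)


def jarzynski_estimate(samples: WorkSampleSet) -> float:
    """``dG = -kT ln< exp(-W_f / kT) >`` via an overflow-safe log-sum-exp."""
    w = samples.forward
    kT = samples.kT
    return float(-kT * (logsumexp(-w / kT) - np.log(w.size)))


def crooks_gaussian_intersection(samples: WorkSampleSet) -> float:
    """Intersection abscissa of Gaussian fits to ``W_f`` and ``-W_r``.

    Gaussians are fitted by sample moments.  With (numerically) equal
    variances the closed form ``(mean(W_f) + mean(-W_r)) / 2`` is used;
    otherwise the quadratic root lying between the two fitted means is
    returned (the physically meaningful crossing).
    """
    if samples.forward.size < 2 or samples.reverse.size < 2:
        raise ValueError("Crooks-Gaussian needs >= 2 samples per direction")
    wf = samples.forward
    wr = -samples.reverse
    mu_f, var_f = float(np.mean(wf)), float(np.var(wf))
    mu_r, var_r = float(np.mean(wr)), float(np.var(wr))
    if var_f <= 0 or var_r <= 0:
        return 0.5 * (mu_f + mu_r)
    # equal-variance closed form when variances agree to within rounding
    if abs(var_f - var_r) <= 1e-12 * max(var_f, var_r):
        return 0.5 * (mu_f + mu_r)
    # intersection of N(mu_f, var_f) and N(mu_r, var_r) densities:
    # quadratic a x^2 + b x + c = 0 in x
    a = 1.0 / var_f - 1.0 / var_r
    b = 2.0 * (mu_r / var_r - mu_f / var_f)
    c = (
        mu_f**2 / var_f
        - mu_r**2 / var_r
        + np.log(var_f / var_r)
    )
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise CrooksIntersectionError([], mu_f, mu_r)
    roots = sorted(
        [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
    )
    lo, hi = sorted([mu_f, mu_r])
    between = [r for r in roots if lo <= r <= hi]
    if not between:
        raise CrooksIntersectionError(roots, mu_f, mu_r)
    return float(between[0])


# ---------------------------------------------------------------------------
# thermodynamic cycle
# ---------------------------------------------------------------------------

VALID_STATES = {"wt", "mutant", "difference"}


@dataclass(frozen=True)
class FreeEnergyLeg:
    """One free-energy leg of the cycle.

    ``state`` is ``wt`` or ``mutant`` for a physical leg, or ``difference``
    when the value already is the mutant-minus-wt difference for that
    process (e.g. taken from an alchemical route).
    """

    process: str  # e.g. ins | N-dimer | C-dimer | pose
    state: str
    value: float  # kJ/mol
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(
                f"state must be one of {sorted(VALID_STATES)}, "
                f"got {self.state!r}"
            )
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


class MissingLegError(ValueError):
    """A process lacks the leg needed to close the cycle."""


@dataclass
class ThermodynamicCycle:
    """Assembled cycle: per-process ddG values and loop-closure residuals."""

    legs: list[FreeEnergyLeg]
    ddg: dict[str, float]
    ddg_uncertainty: dict[str, float]
    residuals: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "process": list(self.ddg),
                "ddG_kJ_mol": [self.ddg[p] for p in self.ddg],
                "uncertainty_kJ_mol": [
                    self.ddg_uncertainty[p] for p in self.ddg
                ],
            }
        )


def legs_from_tsv(path: str | Path) -> list[FreeEnergyLeg]:
    df = pd.read_csv(path, sep="\t")
    unc = df["uncertainty"] if "uncertainty" in df.columns else 0.0
    df = df.assign(uncertainty=unc)
    return [
        FreeEnergyLeg(
            str(r.process), str(r.state), float(r.value), float(r.uncertainty)
        )
        for r in df.itertuples()
    ]


def assemble_cycle(legs: list[FreeEnergyLeg]) -> ThermodynamicCycle:
    """Derive per-process ddG values and cycle-closure residuals.

    For each process with ``wt`` and ``mutant`` legs,
    ``ddG = dG_mutant - dG_wt`` (uncertainties propagated in quadrature);
    ``difference`` legs contribute their value directly.  The pose-change
    difference is derived as ``ddG[pose] = ddG[C-dimer] - ddG[N-dimer]``
    whenever both dimer processes are present.  Closure residuals are
    reported for every loop that the provided legs close:

    * per state, ``dG[pose] - (dG[C-dimer] - dG[N-dimer])`` when an explicit
      pose leg exists, and
    * ``ddG[pose] - (ddG[C-dimer] - ddG[N-dimer])`` when an explicit pose
      difference was supplied alongside both dimer differences.
    """
    by_process: dict[str, dict[str, FreeEnergyLeg]] = {}
    for leg in legs:
        slot = by_process.setdefault(leg.process, {})
        if leg.state in slot:
            raise ValueError(
                f"duplicate leg for process {leg.process!r}, "
                f"state {leg.state!r}"
            )
        slot[leg.state] = leg

    ddg: dict[str, float] = {}
    unc: dict[str, float] = {}
    for process, slot in by_process.items():
        if "difference" in slot:
            if "wt" in slot or "mutant" in slot:
                raise ValueError(
                    f"process {process!r} mixes a difference leg with "
                    "physical legs"
                )
            ddg[process] = slot["difference"].value
            unc[process] = slot["difference"].uncertainty
        else:
            missing = {"wt", "mutant"} - set(slot)
            if missing:
                raise MissingLegError(
                    f"process {process!r} is missing the "
                    f"{sorted(missing)[0]} leg"
                )
            ddg[process] = slot["mutant"].value - slot["wt"].value
            unc[process] = float(
                np.hypot(slot["mutant"].uncertainty, slot["wt"].uncertainty)
            )

    residuals: dict[str, float] = {}
    explicit_pose = "pose" in ddg
    if {"N-dimer", "C-dimer"} <= set(ddg):
        derived_pose = ddg["C-dimer"] - ddg["N-dimer"]
        derived_unc = float(np.hypot(unc["C-dimer"], unc["N-dimer"]))
        if explicit_pose:
            residuals["ddG_pose_loop"] = ddg["pose"] - derived_pose
        else:
            ddg["pose"] = derived_pose
            unc["pose"] = derived_unc
        # per-state loops, when physical legs exist for all three processes
        for state in ("wt", "mutant"):
            procs = (by_process.get("pose", {}), by_process.get("N-dimer", {}),
                     by_process.get("C-dimer", {}))
            if all(state in p for p in procs):
                residuals[f"dG_pose_loop_{state}"] = procs[0][state].value - (
                    procs[2][state].value - procs[1][state].value
                )
    return ThermodynamicCycle(
        legs=list(legs), ddg=ddg, ddg_uncertainty=unc, residuals=residuals
    )
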