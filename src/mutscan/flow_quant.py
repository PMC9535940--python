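"""Gating and geometric-mean quantitation of two-channel flow events.

Gates operate in log10 signal space (flow-data convention).  Events with a
non-positive signal in either channel are dropped on construction (with the
dropped count recorded) because geometric statistics require positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FlowEventSet:
    """Per-event (expression, phospho) signal pairs with a population label.

    ``n_dropped`` counts events removed for non-positive signals.
    """

    data: pd.DataFrame  # columns: expression, phospho, label
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"expression", "phospho"}
        if not required <= set(self.data.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        if "label" not in self.data.columns:
            self.data = self.data.assign(label="sample")
        ok = (self.data["expression"] > 0) & (self.data["phospho"] > 0)
        if not ok.all():
            self.n_dropped += int((~ok).sum())
            self.data = self.data.loc[ok].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def expression(self) -> np.ndarray:
        return self.data["expression"].to_numpy(dtype=float)

    @property
    def phospho(self) -> np.ndarray:
        return self.data["phospho"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowEventSet":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class RectGate:
    """Rectangular gate with half-open [lo, hi) bounds in log10 space.

    ``None`` bounds are unbounded on that side; the phospho channel is
    unbounded by default (the typical expression gate).
    """

    expr_lo: float | None = None
    expr_hi: float | None = None
    phospho_lo: float | None = None
    phospho_hi: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in ((self.expr_lo, self.expr_hi),
                       (self.phospho_lo, self.phospho_hi)):
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError("gate bounds must satisfy lo < hi")

    def mask(self, events: FlowEventSet) -> np.ndarray:
        le = np.log10(events.expression)
        lp = np.log10(events.phospho)
        m = np.ones(len(events), dtype=bool)
        if self.expr_lo is not None:
            m &= le >= self.expr_lo
        if self.expr_hi is not None:
            m &= le < self.expr_hi
        if self.phospho_lo is not None:
            m &= lp >= self.phospho_lo
        if self.phospho_hi is not None:
            m &= lp < self.phospho_hi
        return m


@dataclass(frozen=True)
class DiagGate:
    """Diagonal gate ``log10(phospho) - m * log10(expression) > c``.

    ``side`` selects which half-plane is kept.
    """

    slope: float
    intercept: float
    side: str = "above"

    def __post_init__(self) -> None:
        if self.side not in ("above", "below"):
            raise ValueError("side must be 'above' or 'below'")

    def mask(self, events: FlowEventSet) -> np.ndarray:
        score = (
            np.log10(events.phospho)
            - self.slope * np.log10(events.expression)
        )
        return score > self.intercept if self.side == "above" \
            else score < self.intercept


def gate_rectangular(events: FlowEventSet, gate: RectGate) -> FlowEventSet:
    """Subset of events inside the rectangular gate (may be empty)."""
    sub = events.data.loc[gate.mask(events)].reset_index(drop=True)
    return FlowEventSet(sub)


def gate_diagonal(events: FlowEventSet, gate: DiagGate) -> FlowEventSet:
    """Subset of events on the selected side of the diagonal gate."""
    sub = events.data.loc[gate.mask(events)].reset_index(drop=True)
    return FlowEventSet(sub)


def gmfi(values) -> float:
    """Geometric mean fluorescence intensity: ``exp(mean(log(values)))``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gmfi of an empty sample is undefined")
    if (v <= 0).any():
        raise ValueError("gmfi requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-tailed paired t-test on ``a - b``.

    Degenerate inputs follow the documented limits: all differences zero
    gives ``(0, 1)``; zero-variance differences with a nonzero mean give
    ``(+/-inf, 0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equal-length 1-d samples")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean)) * np.inf, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class ActivationResult:
    """Background-subtracted, wild-type-normalized activation per replicate."""

    per_replicate: np.ndarray
    mean: float
    sd: float
    t_statistic: float | None = None
    p_value: float | None = None

    def __str__(self) -> str:
        s = f"activation = {self.mean:.3f} +/- {self.sd:.3f}"
        if self.p_value is not None:
            s += f" (p = {self.p_value:.3g} vs wt)"
        return s


def normalize_activation(
    gmfi_sample,
    gmfi_background,
    gmfi_wt,
    gmfi_wt_background,
    test_vs_wt: bool = True,
) -> ActivationResult:
    """Per-replicate normalized activation with replicate mean +/- SD.

    ``activation = (gmfi_sample - gmfi_background) /
    (gmfi_wt - gmfi_wt_background)`` computed replicate by replicate, then
    aggregated.  When >= 2 replicates are available and ``test_vs_wt``,
    a two-tailed paired t-test against the wild type (activation 1 by
    construction) is attached.
    """
    s = np.atleast_1d(np.asarray(gmfi_sample, dtype=float))
    bg = np.broadcast_to(
        np.atleast_1d(np.asarray(gmfi_background, dtype=float)), s.shape
    )
    wt = np.broadcast_to(
        np.atleast_1d(np.asarray(gmfi_wt, dtype=float)), s.shape
    )
    wt_bg = np.broadcast_to(
        np.atleast_1d(np.asarray(gmfi_wt_background, dtype=float)), s.shape
    )
    net_wt = wt - wt_bg
    if (net_wt <= 0).any():
        raise ValueError(
            "non-positive wild-type net signal; normalization undefined"
        )
    act = (s - bg) / net_wt
    mean = float(act.mean())
    sd = float(act.std(ddof=1)) if act.size > 1 else 0.0
    t = p = None
    if test_vs_wt and act.size >= 2:
        t, p = paired_t_test(act, np.ones_like(act))
    return ActivationResult(
        per_replicate=act, mean=mean, sd=sd, t_statistic=t, p_value=p
    )


# ---------------------------------------------------------------------------
# bead calibration
# ---------------------------------------------------------------------------


@dataclass
class BeadCalibration:
    """log10(molecules) = slope * log10(intensity) + intercept."""

    slope: float
    intercept: float
    warnings: list[str] = field(default_factory=list)

    def apply(self, gmfi_value: float) -> float:
        """Map a gMFI value to molecules per cell."""
        if gmfi_value <= 0:
            raise ValueError("gMFI must be positive")
        return float(
            10.0 ** (self.slope * np.log10(gmfi_value) + self.intercept)
        )


def quantibrite_calibrate(
    bead_intensities, bead_molecule_counts
) -> BeadCalibration:
    """Least-squares fit of log10(molecules) vs log10(intensity)."""
    x = np.asarray(bead_intensities, dtype=float)
    y = np.asarray(bead_molecule_counts, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 matched bead levels")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("bead intensities and counts must be positive")
    warns = []
    if np.unique(x).size < x.size:
        warns.append("duplicate bead intensities at different counts")
    slope, intercept = np.polyfit(np.log10(x), np.log10(y), deg=1)
    return BeadCalibration(float(slope), float(intercept), warns)
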