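"""Sequential flow-cytometry gating of converted vs. unconverted microglia.

The gate chain mirrors the standard microglia sorting strategy:
singlets (FSC-A/FSC-H) → live (viability dye negative) → CD45⁺ CD11b⁺ →
high green fluorescence (Cx3cr1-driven expression; excludes peripheral
monocytes) → classification into green-only (gD2) vs. green/red
double-positive (rD2) microglia.  rD2 cells keep residual green protein
after conversion, which is what holds them above the high-green gate.

Cutoffs are configuration, not constants: the defaults sit at the valleys
between the synthetic generator's log-normal clusters, and all are
exposed so real-instrument thresholds can substitute.  A simple linear
spillover inversion is available for compensation (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dendratrack.synthetic_data import FLOW_CHANNELS, FlowEventTable

GATE_SEQUENCE = ["singlets", "live", "cd45_cd11b", "high_green"]


@dataclass(frozen=True)
class GateConfig:
    singlet_ratio_bounds: tuple[float, float] = (0.7, 1.4)
    viability_max: float = 2_000.0
    cd45_min: float = 1_000.0
    cd11b_min: float = 1_000.0
    green_high_min: float = 1_000.0
    red_pos_min: float = 500.0
    spillover: np.ndarray = field(
        default_factory=lambda: np.eye(2))  # rows/cols: (green, red)

    def __post_init__(self) -> None:
        lo, hi = self.singlet_ratio_bounds
        if not lo < hi:
            raise ValueError("singlet ratio bounds must be ordered")
        s = np.asarray(self.spillover, dtype=float)
        if s.shape != (2, 2):
            raise ValueError("spillover must be 2×2 (green, red)")
        off = s[~np.eye(2, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("off-diagonal spillover must be in [0, 1)")
        if abs(np.linalg.det(s)) < 1e-12:
            raise ValueError("spillover matrix is singular")


@dataclass
class GatingResult:
    n_total: int
    n_after: dict[str, int]          # ordered per GATE_SEQUENCE
    n_gd2: int
    n_rd2: int

    def __post_init__(self) -> None:
        counts = [self.n_total] + [self.n_after[g] for g in GATE_SEQUENCE]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("gate counts must be non-increasing")
        if self.n_gd2 + self.n_rd2 != self.n_after[GATE_SEQUENCE[-1]]:
            raise ValueError("gD2 + rD2 must equal the final gated count")

    @property
    def frac_rd2(self) -> float:
        """rD2 fraction of the final (high-green microglia) gate."""
        denom = self.n_gd2 + self.n_rd2
        return self.n_rd2 / denom if denom else float("nan")

    @property
    def frac_rd2_of_myeloid(self) -> float:
        """rD2 fraction with the CD45⁺CD11b⁺ gate as denominator."""
        denom = self.n_after["cd45_cd11b"]
        return self.n_rd2 / denom if denom else float("nan")


def compensate(table: FlowEventTable, spillover: np.ndarray
               ) -> tuple[FlowEventTable, int]:
    """Invert a linear green↔red spillover; negatives are clipped to 0.

    Returns the corrected table and the number of clipped events.
    """
    s = np.asarray(spillover, dtype=float)
    if s.shape != (2, 2) or abs(np.linalg.det(s)) < 1e-12:
        raise ValueError("spillover must be an invertible 2×2 matrix")
    inv = np.linalg.inv(s)
    gr = table.events[["green", "red"]].to_numpy()
    corrected = gr @ inv.T
    n_clipped = int(np.sum(np.any(corrected < 0, axis=1)))
    corrected = np.clip(corrected, 0.0, None)
    events = table.events.copy()
    events[["green", "red"]] = corrected
    return FlowEventTable(events=events,
                          true_population=table.true_population), n_clipped


def apply_gates(table: FlowEventTable,
                config: GateConfig = GateConfig()) -> GatingResult:
    """Run the sequential gate chain and classify survivors by red signal."""
    required = set(FLOW_CHANNELS)
    missing = required - set(table.events.columns)
    if missing:
        raise ValueError(f"missing event columns: {sorted(missing)}")
    ev = table.events
    lo, hi = config.singlet_ratio_bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ev["fsc_a"] / ev["fsc_h"]
    masks = {}
    current = ratio.between(lo, hi).fillna(False)
    masks["singlets"] = current
    current = current & (ev["viability"] <= config.viability_max)
    masks["live"] = current
    current = current & (ev["cd45"] >= config.cd45_min) \
                      & (ev["cd11b"] >= config.cd11b_min)
    masks["cd45_cd11b"] = current
    current = current & (ev["green"] >= config.green_high_min)
    masks["high_green"] = current

    red_pos = ev["red"] >= config.red_pos_min
    n_rd2 = int((current & red_pos).sum())
    n_gd2 = int((current & ~red_pos).sum())
    return GatingResult(
        n_total=len(ev),
        n_after={g: int(m.sum()) for g, m in masks.items()},
        n_gd2=n_gd2, n_rd2=n_rd2)


def microglia_confusion(table: FlowEventTable,
                        config: GateConfig = GateConfig()
                        ) -> dict[str, float]:
    """Precision/recall of the gate chain against simulator ground truth.

    "Microglia" ground truth = gD2 + rD2 microglia labels; prediction =
    events surviving the full gate chain.
    """
    ev = table.events
    lo, hi = config.singlet_ratio_bounds
    pred = (ev["fsc_a"] / ev["fsc_h"]).between(lo, hi) \
        & (ev["viability"] <= config.viability_max) \
        & (ev["cd45"] >= config.cd45_min) \
        & (ev["cd11b"] >= config.cd11b_min) \
        & (ev["green"] >= config.green_high_min)
    truth = table.true_population.isin(["gD2_microglia", "rD2_microglia"])
    tp = int((pred & truth).sum())
    precision = tp / int(pred.sum()) if pred.sum() else float("nan")
    recall = tp / int(truth.sum()) if truth.sum() else float("nan")
    return {"precision": precision, "recall": recall}


def compare_samples(results: list[GatingResult], groups: list[str]
                    ) -> pd.DataFrame:
    """Per-group mean ± standard error of the rD2 fraction.

    Each result is one retina (the experimental unit); a single-sample
    group reports its value with SE missing (NaN).
    """
    if len(results) != len(groups) or not results:
        raise ValueError("need one group label per gating result")
    df = pd.DataFrame({"group": groups,
                       "frac_rd2": [r.frac_rd2 for r in results]})
    if df.groupby("group").size().min() < 1:
        raise ValueError("every group needs at least one sample")
    summary = df.groupby("group")["frac_rd2"].agg(
        mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x))
        if len(x) > 1 else np.nan, n="size")
    return summary.reset_index()
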