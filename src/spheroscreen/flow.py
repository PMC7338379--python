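"""Annexin-V flow-cytometry simulation, gating and viability labelling.

Apoptotic cells expose phosphatidylserine and bind Annexin-V, so in a
single-marker cytometry readout the apoptotic (dead/dying) population sits at
high fluorescence and the live population at low fluorescence. Because a
single spheroid yields too few cells for cytometry, pools of equally treated
spheroids are dissociated and measured together; the pool-level live fraction
is then used as the label for every image from that pool.

Event intensities are modelled as a two-component log-normal mixture — the
standard shape of flow fluorescence histograms — parameterized by the
component medians (``live_mu``, ``dead_mu``, arbitrary fluorescence units)
and a shared log-scale ``sigma``. Gating is a single intensity threshold:
events below the gate count as live. The default gate is the geometric
midpoint ``sqrt(live_mu * dead_mu)``, i.e. halfway between the component
medians on the log scale.

Labels follow the three-category viability scheme:

* live fraction  > 0.80          -> ``unaffected``
* live fraction in [0.40, 0.60]  -> ``mildly_affected``
* live fraction  < 0.40          -> ``affected``
* anywhere else (the (0.60, 0.80] band) -> ``unlabeled``

The boundary conventions make the three printed inequalities non-overlapping:
0.80 itself is *not* unaffected, 0.40 and 0.60 belong to mildly_affected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FlowEventTable",
    "ViabilityResult",
    "simulate_events",
    "gate_viability",
    "label_from_viability",
    "default_gate",
    "CLASS_VIABILITY_RANGES",
    "DEFAULT_LIVE_MU",
    "DEFAULT_DEAD_MU",
    "DEFAULT_SIGMA",
]

DEFAULT_LIVE_MU = 100.0  # median Annexin-V intensity of live events (a.u.)
DEFAULT_DEAD_MU = 10_000.0  # median intensity of apoptotic events (a.u.)
DEFAULT_SIGMA = 0.4  # shared log-normal scale (natural-log units)

# Viability ranges used when sampling per-class ground truth. They sit a
# small margin inside the label bands so that binomial gating noise on a
# finite event count cannot flip a pool across a label boundary.
CLASS_VIABILITY_RANGES = {
    "unaffected": (0.82, 0.98),
    "mildly_affected": (0.42, 0.58),
    "affected": (0.05, 0.38),
}


@dataclass
class FlowEventTable:
    """Per-pool Annexin-V event intensities (one float per cell event)."""

    events: np.ndarray
    pool_id: str = "pool"

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float).ravel()
        if self.events.size and np.any(self.events <= 0):
            raise ValueError("all event intensities must be positive")

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pool_id": self.pool_id, "annexin_intensity": self.events}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pool_id: Optional[str] = None) -> "FlowEventTable":
        if pool_id is not None:
            df = df[df["pool_id"] == pool_id]
        else:
            ids = df["pool_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple pools; pass pool_id")
            pool_id = str(ids[0])
        return cls(events=df["annexin_intensity"].to_numpy(), pool_id=str(pool_id))


@dataclass(frozen=True)
class ViabilityResult:
    """Gated live fraction plus the derived three-category label."""

    live_fraction: float
    gate_threshold: float
    label: str
    pool_id: str = "pool"

    def __post_init__(self) -> None:
        if not 0.0 <= self.live_fraction <= 1.0:
            raise ValueError("live_fraction must lie in [0, 1]")


def default_gate(live_mu: float = DEFAULT_LIVE_MU, dead_mu: float = DEFAULT_DEAD_MU) -> float:
    """Geometric midpoint between the live and apoptotic component medians."""
    return float(np.sqrt(live_mu * dead_mu))


def simulate_events(
    live_fraction: float,
    n_events: int,
    live_mu: float = DEFAULT_LIVE_MU,
    dead_mu: float = DEFAULT_DEAD_MU,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    pool_id: str = "pool",
) -> FlowEventTable:
    """Draw a two-component log-normal Annexin-V intensity mixture.

    Each event is live with probability ``live_fraction`` (drawn from the
    low-intensity component with median ``live_mu``), otherwise apoptotic
    (median ``dead_mu`` > ``live_mu``). Reproducible under ``seed``.
    """
    if not 0.0 <= live_fraction <= 1.0:
        raise ValueError("live_fraction must lie in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if dead_mu <= live_mu:
        raise ValueError("dead_mu must exceed live_mu (Annexin-V-positive = brighter)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    is_live = rng.random(n_events) < live_fraction
    log_mu = np.where(is_live, np.log(live_mu), np.log(dead_mu))
    events = np.exp(rng.normal(log_mu, sigma))
    return FlowEventTable(events=events, pool_id=pool_id)


def gate_viability(table: FlowEventTable, gate_threshold: Optional[float] = None) -> ViabilityResult:
    """Gate a pool: live fraction = share of events below the gate threshold."""
    if table.n_events == 0:
        raise ValueError("empty event table: viability undefined")
    if gate_threshold is None:
        gate_threshold = default_gate()
    if gate_threshold <= 0:
        raise ValueError("gate_threshold must be positive")
    live_fraction = float(np.mean(table.events < gate_threshold))
    return ViabilityResult(
        live_fraction=live_fraction,
        gate_threshold=float(gate_threshold),
        label=label_from_viability(live_fraction),
        pool_id=table.pool_id,
    )


def label_from_viability(live_fraction: float) -> str:
    """Map a live fraction in [0, 1] onto the three-category scheme.

    >0.80 -> unaffected; [0.40, 0.60] -> mildly_affected; <0.40 -> affected;
    the uncovered band (0.60, 0.80] -> unlabeled.
    """
    if not 0.0 <= live_fraction <= 1.0:
        raise ValueError(f"live_fraction {live_fraction} outside [0, 1]")
    if live_fraction > 0.80:
        return "unaffected"
    if 0.40 <= live_fraction <= 0.60:
        return "mildly_affected"
    if live_fraction < 0.40:
        return "affected"
    return "unlabeled"


def viability_results_to_frame(results: list[ViabilityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pool_id": [r.pool_id for r in results],
            "live_fraction": [r.live_fraction for r in results],
            "label": [r.label for r in results],
        }
    )
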