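"""Standardized sampling of a community, plant individual by plant individual.

Mimics the field protocol: plants are censused one at a time in random
order without replacement; each sampled plant reveals at most one herbivore
and at most one enemy.  Interaction diversity accumulates over the sample
as the inverse Simpson index of the interaction-event counts seen so far.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TritrophError
from .webgen import InteractionTable

__all__ = ["SampleSequence", "AccumulationCurve", "sample_community", "accumulate"]

NETWORKS = ("PH", "HE", "PHE")
METRICS = ("richness", "inv_simpson")


@dataclass
class SampleSequence:
    """A full random sampling order over one community's plant individuals."""

    table: InteractionTable
    order: np.ndarray  # permutation of row positions in table.frame

    def __len__(self) -> int:
        return len(self.order)

    def rows(self) -> pd.DataFrame:
        """The interaction table in sampled order."""
        return self.table.frame.iloc[self.order].reset_index(drop=True)

    def interaction_rows(self) -> pd.DataFrame:
        """Sampled-order rows that carry at least one interaction."""
        rows = self.rows()
        return rows[rows["herb_sp"].notna()].reset_index(drop=True)


@dataclass
class AccumulationCurve:
    """Cumulative metric value after each sampled plant individual.

    ``y`` is NaN before the first observed interaction of the network type;
    afterwards rows without a qualifying interaction carry the previous
    value forward, so x stays in units of sampling effort.
    """

    network: str
    metric: str
    x: np.ndarray
    y: np.ndarray

    def final(self) -> float:
        return float(self.y[-1])


def sample_community(
    table: InteractionTable, rng: np.random.Generator | None = None
) -> SampleSequence:
    """Draw a uniform random sampling order (without replacement)."""
    if len(table) == 0:
        raise TritrophError("cannot sample an empty interaction table")
    rng = np.random.default_rng() if rng is None else rng
    order = rng.permutation(len(table))
    return SampleSequence(table=table, order=order)


def interaction_key(row, network: str):
    """The interaction-type identity of one sampled row, or None.

    PH and HE types are ordered species pairs; PHE types are complete
    ordered triples (rows lacking the enemy do not form a PHE type).
    """
    plant, herb, enemy = row
    no_herb = pd.isna(herb)
    no_enemy = pd.isna(enemy)
    if network == "PH":
        return None if no_herb else (plant, herb)
    if network == "HE":
        return None if no_enemy else (herb, enemy)
    if network == "PHE":
        return None if no_enemy else (plant, herb, enemy)
    raise ValueError(f"unknown network {network!r}")


def accumulate(seq: SampleSequence, metric: str, network: str) -> AccumulationCurve:
    """Accumulation curve of richness or inverse Simpson diversity.

    The inverse Simpson index of the counts seen so far is updated
    incrementally (n^2 / sum of squared counts), so the full curve costs
    O(sample size).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if network not in NETWORKS:
        raise ValueError(f"network must be one of {NETWORKS}")

    rows = seq.rows()
    triples = list(zip(rows["plant_sp"], rows["herb_sp"], rows["enemy_sp"]))
    n = len(triples)
    y = np.full(n, np.nan)
    counts: dict = {}
    total = 0
    sumsq = 0
    for i, row in enumerate(triples):
        key = interaction_key(row, network)
        if key is not None:
            c = counts.get(key, 0)
            counts[key] = c + 1
            sumsq += 2 * c + 1
            total += 1
        if total > 0:
            y[i] = len(counts) if metric == "richness" else total * total / sumsq
    return AccumulationCurve(network=network, metric=metric,
                             x=np.arange(1, n + 1), y=y)


def accumulation_frame(
    seq: SampleSequence, web_id=None,
    metrics=METRICS, networks=NETWORKS,
) -> pd.DataFrame:
    """Long-format accumulation curves: web_id, network, step, metric, value."""
    parts = []
    for network in networks:
        for metric in metrics:
            curve = accumulate(seq, metric, network)
            parts.append(pd.DataFrame({
                "web_id": web_id, "network": network,
                "step": curve.x, "metric": metric, "value": curve.y,
            }))
    return pd.concat(parts, ignore_index=True)
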