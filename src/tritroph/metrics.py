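"""Per-community summary metrics feeding the statistical layer.

One row per simulated community.  Conventions:

* interaction diversity per network view = inverse Simpson over the
  interaction-type event counts (pairs for PH/HE, complete triples for
  PHE);
* species diversity for a two-level view (PH, HE) = inverse Simpson over
  the individuals participating in that view's interaction events (both
  partners of every event); for the complete PHE view it is the community
  species diversity — every realized individual across the three levels —
  which is what makes the species/interaction relationship much looser for
  PHE than for the two-level views;
* Chao1 and rarefaction "species" use the generated (pre-assembly)
  species-abundance distribution of the view's trophic levels, while
  "interactions" use the realized event counts;
* the richness and abundance covariates sum species and individuals over
  the trophic levels as observed within the view's interaction events.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from . import diversity
from .errors import EmptyNetworkError
from .netmetrics import build_matrices, connectance
from .webgen import Community

__all__ = [
    "NETWORK_LEVELS",
    "interaction_counts",
    "participant_counts",
    "species_counts",
    "initial_species_counts",
    "web_metrics",
    "compute_metrics_table",
    "rarefaction_slopes",
    "sample_metrics",
]

# trophic levels whose species make up each network view
NETWORK_LEVELS = {"PH": (1, 2), "HE": (2, 3), "PHE": (1, 2, 3)}
# interaction-table columns observed in each view's events
NETWORK_COLUMNS = {
    "PH": ("plant_sp", "herb_sp"),
    "HE": ("herb_sp", "enemy_sp"),
    "PHE": ("plant_sp", "herb_sp", "enemy_sp"),
}


def _event_rows(frame: pd.DataFrame, network: str) -> pd.DataFrame:
    col = "herb_sp" if network == "PH" else "enemy_sp"
    return frame.dropna(subset=[col])


def interaction_counts(frame: pd.DataFrame, network: str) -> Counter:
    """Event counts per interaction type (pair or complete triple)."""
    if network not in NETWORK_COLUMNS:
        raise ValueError(f"unknown network {network!r}")
    sub = _event_rows(frame, network)
    return Counter(zip(*(sub[c] for c in NETWORK_COLUMNS[network])))


def participant_counts(frame: pd.DataFrame, network: str) -> Counter:
    """Individual counts per species over a view's interaction events."""
    sub = _event_rows(frame, network)
    counts: Counter = Counter()
    for col in NETWORK_COLUMNS[network]:
        counts.update(sub[col].dropna())
    return counts


def species_counts(community: Community, levels=(1, 2, 3)) -> np.ndarray:
    """Realized individual counts of every species in the given levels."""
    parts = [community.abundances[lvl].to_numpy() for lvl in levels
             if lvl in community.abundances and len(community.abundances[lvl])]
    if not parts:
        return np.array([], dtype=np.int64)
    return np.concatenate(parts)


def initial_species_counts(community: Community, levels=(1, 2, 3)) -> np.ndarray:
    """Generated (pre-assembly) individual counts for the given levels."""
    parts = [community.initial_abundances[lvl].to_numpy() for lvl in levels
             if lvl in community.initial_abundances
             and len(community.initial_abundances[lvl])]
    if not parts:
        return np.array([], dtype=np.int64)
    return np.concatenate(parts)


def _mean_or_nan(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(values.mean()) if values.size else np.nan


def _present_assigned(community: Community, level: int) -> pd.Series:
    """Assigned diet breadths of the consumer species that survived."""
    assigned = community.assigned_breadths.get(level)
    present = community.abundances.get(level)
    if assigned is None or present is None or not len(assigned) or not len(present):
        return pd.Series(dtype=float)
    return assigned.reindex(present.index).dropna()


def web_metrics(community: Community, web_id=None) -> dict:
    """All whole-web summary metrics for one community."""
    frame = community.table.frame
    out: dict = {"web_id": web_id}

    sp_all = species_counts(community)
    out["species_diversity"] = diversity.inverse_simpson(sp_all) if sp_all.size else np.nan
    out["richness_total"] = sum(community.richness(lvl) for lvl in (1, 2, 3))
    out["abundance_total"] = sum(community.abundance(lvl) for lvl in (1, 2, 3))
    out["plant_abundance"] = community.abundance(1)

    # diet-breadth covariates: the assigned (truncated-Pareto) breadths of
    # the consumer species present in the realized community.  These are
    # the community's specialization parameters and stay exogenous to the
    # assembly outcome; the realized (unique hosts actually used) breadths
    # are reported alongside but are heavily right-censored by pruning.
    herb_a = _present_assigned(community, 2)
    enemy_a = _present_assigned(community, 3)
    out["mean_herb_breadth"] = _mean_or_nan(herb_a)
    out["mean_enemy_breadth"] = _mean_or_nan(enemy_a)
    out["mean_consumer_breadth"] = _mean_or_nan(
        np.concatenate([herb_a.to_numpy(float), enemy_a.to_numpy(float)])
        if len(herb_a) or len(enemy_a) else np.array([])
    )
    herb_r = community.realized_diet_breadths(2)
    enemy_r = community.realized_diet_breadths(3)
    out["mean_herb_breadth_realized"] = _mean_or_nan(herb_r)
    out["mean_enemy_breadth_realized"] = _mean_or_nan(enemy_r)
    out["mean_consumer_breadth_realized"] = _mean_or_nan(
        np.concatenate([herb_r.to_numpy(float), enemy_r.to_numpy(float)])
        if len(herb_r) or len(enemy_r) else np.array([])
    )

    matrices = build_matrices(community.table)
    counts_by_net = {}
    for net in ("PH", "HE", "PHE"):
        ic = interaction_counts(frame, net)
        counts_by_net[net] = ic
        vals = list(ic.values())
        out[f"intdiv_{net}"] = diversity.inverse_simpson(vals) if vals else np.nan
        out[f"intrich_{net}"] = len(ic)

        if net == "PHE":
            out["spdiv_PHE"] = out["species_diversity"]
        else:
            pc = list(participant_counts(frame, net).values())
            out[f"spdiv_{net}"] = diversity.inverse_simpson(pc) if pc else np.nan

        sub = _event_rows(frame, net)
        observed: set = set()
        for col in NETWORK_COLUMNS[net]:
            observed.update(sub[col].dropna())
        out[f"richness_net_{net}"] = len(observed)
        out[f"abundance_net_{net}"] = int(sub[list(NETWORK_COLUMNS[net])].notna()
                                          .to_numpy().sum())

        try:
            out[f"connectance_{net}"] = connectance(matrices[net]).value
        except EmptyNetworkError:
            out[f"connectance_{net}"] = np.nan
        out[f"chao1_int_{net}"] = diversity.chao1(vals).estimate if vals else np.nan
        sp_net = initial_species_counts(community, NETWORK_LEVELS[net])
        out[f"chao1_sp_{net}"] = (
            diversity.chao1(sp_net).estimate if sp_net.size else np.nan
        )

    n_links = len(counts_by_net["PH"]) + len(counts_by_net["HE"])
    out["interaction_density"] = (
        n_links / out["richness_total"] if out["richness_total"] else np.nan
    )
    out["degenerate"] = community.degenerate
    out["no_herbivores"] = community.flags.get("no_herbivores", False)
    out["no_enemies"] = community.flags.get("no_enemies", False)
    return out


def compute_metrics_table(communities, web_ids=None) -> pd.DataFrame:
    """Metrics table with one row per community."""
    if web_ids is None:
        web_ids = range(len(communities))
    rows = [web_metrics(c, i) for i, c in zip(web_ids, communities)]
    return pd.DataFrame(rows)


def rarefaction_slopes(
    community: Community,
    rng: np.random.Generator | None = None,
    networks=("PH", "HE", "PHE"),
    n_resamples: int = 500,
    mode: str = "exact",
) -> dict:
    """Slope-at-half-richness of the species and interaction rarefaction
    curves, per network view.

    ``mode="exact"`` (default) uses the closed-form classical rarefaction
    expectation, which is deterministic; ``mode="bootstrap"`` averages
    ``n_resamples`` with-replacement accumulation curves and needs ``rng``.
    Returns {(network, unit): slope} with unit in {"species",
    "interaction"}; NaN where the network has no events.
    """
    frame = community.table.frame
    out = {}
    for net in networks:
        sp = initial_species_counts(community, NETWORK_LEVELS[net])
        ic = np.array(list(interaction_counts(frame, net).values()), dtype=np.int64)
        for unit, counts in (("species", sp), ("interaction", ic)):
            if counts.size == 0:
                out[(net, unit)] = np.nan
            elif mode == "exact":
                out[(net, unit)] = diversity.hypergeom_slope_at_half_richness(counts)
            elif mode == "bootstrap":
                curve = diversity.rarefy(counts, n_resamples=n_resamples, rng=rng)
                out[(net, unit)] = diversity.slope_at_half_richness(curve, counts.size)
            else:
                raise ValueError("mode must be 'exact' or 'bootstrap'")
    return out


def sample_metrics(rows: pd.DataFrame) -> dict:
    """Endogenous metrics recomputed from a prefix of sampled rows.

    Used by the sample-size sweep: ``rows`` is the first n interaction-
    bearing sampled rows of one community.  Species counts come from the
    individuals actually observed in those rows.
    """
    sp = Counter(rows["plant_sp"])
    sp.update(rows["herb_sp"].dropna())
    sp.update(rows["enemy_sp"].dropna())

    phe = interaction_counts(rows, "PHE")
    n_links = len(interaction_counts(rows, "PH")) + len(interaction_counts(rows, "HE"))
    return {
        "species_diversity": diversity.inverse_simpson(list(sp.values())) if sp else np.nan,
        "intdiv_PHE": diversity.inverse_simpson(list(phe.values())) if phe else np.nan,
        "interaction_density": n_links / len(sp) if sp else np.nan,
    }
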