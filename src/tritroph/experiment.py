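"""Orchestration of the headline study.

Generates ``n_webs`` random communities from the configured parameter
ranges, computes per-web metrics, and runs the full analysis stack:
species-vs-interaction correlations, residual regressions, Bayesian
two-group comparisons of Chao1 estimates and rarefaction slopes, the
recursive path model, and the path-coefficient-vs-sample-size sweep.

Per-web seeds are derived from the master seed through a splittable
``SeedSequence`` tree keyed by web index, so web i is identical whether 10
or 10,000 webs are generated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, metrics as metrics_mod
from .errors import DegenerateCommunityError, TritrophError
from .sampling import sample_community
from .webgen import Community, ParameterRanges, draw_config, generate_community

__all__ = [
    "ExperimentConfig",
    "ExperimentResults",
    "run_experiment",
    "generate_webs",
    "FULL_PATH_EDGES",
    "SWEEP_PATH_EDGES",
]

log = logging.getLogger("tritroph")

# A-priori recursive structure: three exogenous community properties
# (plant abundance, mean herbivore and enemy diet breadth) drive four
# endogenous network metrics.  Omitting herb/enemy breadth -> connectance,
# the species-diversity/interaction-density residual covariance and
# interaction-density -> interaction-diversity leaves 4 degrees of freedom.
FULL_PATH_EDGES = [
    ("plant_abundance", "species_diversity"),
    ("mean_herb_breadth", "species_diversity"),
    ("mean_enemy_breadth", "species_diversity"),
    ("plant_abundance", "interaction_density"),
    ("mean_herb_breadth", "interaction_density"),
    ("mean_enemy_breadth", "interaction_density"),
    ("plant_abundance", "connectance_PHE"),
    ("species_diversity", "connectance_PHE"),
    ("interaction_density", "connectance_PHE"),
    ("plant_abundance", "intdiv_PHE"),
    ("mean_herb_breadth", "intdiv_PHE"),
    ("mean_enemy_breadth", "intdiv_PHE"),
    ("species_diversity", "intdiv_PHE"),
    ("connectance_PHE", "intdiv_PHE"),
]

# the sweep refits the same structure without connectance (2 df)
SWEEP_PATH_EDGES = [e for e in FULL_PATH_EDGES if "connectance_PHE" not in e]

EXOGENOUS_COLS = ["plant_abundance", "mean_herb_breadth", "mean_enemy_breadth"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study configuration; defaults are the headline conditions."""

    n_webs: int = 1000
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    seed: int = 0
    n_resamples: int = 500
    rarefaction_mode: str = "exact"
    rarefaction_networks: tuple[str, ...] = ("PH", "HE", "PHE")
    sweep_sizes: tuple[int, ...] = inference.DEFAULT_SWEEP_SIZES
    min_webs_per_size: int = 30
    best_draws: int = 1000
    best_tune: int = 1000
    max_degenerate_frac: float = 0.5
    run_rarefaction: bool = True
    run_best: bool = True
    run_path_model: bool = True
    run_sweep: bool = True

    def __post_init__(self) -> None:
        if self.n_webs < 1:
            raise TritrophError("n_webs must be >= 1")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranges"] = dataclasses.asdict(self.ranges)
        return d


@dataclass
class ExperimentResults:
    """All tables produced by one run; ``write`` dumps them to a directory."""

    config: ExperimentConfig
    metrics: pd.DataFrame
    correlations: pd.DataFrame | None = None
    residual_regressions: pd.DataFrame | None = None
    best: pd.DataFrame | None = None
    path: inference.PathResults | None = None
    sweep: pd.DataFrame | None = None
    n_failed: int = 0

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        if self.correlations is not None:
            self.correlations.to_csv(out / "correlations.csv")
        if self.residual_regressions is not None:
            self.residual_regressions.to_csv(out / "residual_regressions.csv",
                                             index=False)
        if self.best is not None:
            self.best.to_csv(out / "best_comparisons.csv", index=False)
        if self.path is not None:
            self.path.coefficients_frame().to_csv(out / "path_coefficients.csv",
                                                  index=False)
            fit = {"chi_square": self.path.chi_square, "df": self.path.df,
                   "p_value": self.path.p_value, "aic": self.path.aic,
                   "n_obs": self.path.n_obs}
            (out / "path_fit.json").write_text(json.dumps(fit, indent=2))
        if self.sweep is not None:
            self.sweep.to_csv(out / "sweep.csv", index=False)
        manifest = {
            "config": self.config.to_json_dict(),
            "n_webs_generated": int(len(self.metrics)),
            "n_failed": int(self.n_failed),
            "n_degenerate": int(self.metrics["degenerate"].sum()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_webs(
    n_webs: int,
    ranges: ParameterRanges | None = None,
    seed: int = 0,
) -> tuple[list[Community], list[np.random.SeedSequence], int]:
    """Generate communities with per-web seed streams.

    Returns (communities, per-web seed-stream triples, count of failed
    webs).  Each web gets three fixed substreams (generation, rarefaction,
    sampling) spawned once from its index-keyed child sequence, so streams
    do not depend on which analyses later run.  Webs whose plant level
    rounds entirely to zero abundance are counted as failed and skipped
    (they carry no sampling unit at all); webs that merely lack herbivores
    or enemies are retained and flagged.
    """
    ranges = ranges or ParameterRanges()
    children = np.random.SeedSequence(seed).spawn(n_webs)
    communities: list[Community] = []
    kept_streams: list[list[np.random.SeedSequence]] = []
    n_failed = 0
    for child in children:
        sub = child.spawn(3)  # generation / rarefaction / sampling streams
        rng = np.random.default_rng(sub[0])
        config = draw_config(ranges, rng)
        try:
            communities.append(generate_community(config))
            kept_streams.append(sub)
        except DegenerateCommunityError:
            n_failed += 1
    return communities, kept_streams, n_failed


def run_experiment(config: ExperimentConfig) -> ExperimentResults:
    """Run the whole pipeline for one configuration (deterministic)."""
    communities, streams, n_failed = generate_webs(
        config.n_webs, config.ranges, config.seed
    )
    if not communities:
        raise TritrophError("no communities could be generated")

    table = metrics_mod.compute_metrics_table(communities)
    table["web_id"] = range(len(communities))

    frac_deg = table["degenerate"].mean()
    log.info("generated %d webs (%d failed, %.1f%% degenerate)",
             len(communities), n_failed, 100 * frac_deg)
    if frac_deg > config.max_degenerate_frac:
        raise TritrophError(
            f"{100 * frac_deg:.0f}% of webs are degenerate "
            f"(> {100 * config.max_degenerate_frac:.0f}%); check parameter ranges"
        )

    if config.run_rarefaction:
        slope_rows = []
        for community, sub in zip(communities, streams):
            rng = np.random.default_rng(sub[1])
            slopes = metrics_mod.rarefaction_slopes(
                community, rng, networks=config.rarefaction_networks,
                n_resamples=config.n_resamples, mode=config.rarefaction_mode,
            )
            slope_rows.append({f"slope_{'sp' if unit == 'species' else 'int'}_{net}": v
                               for (net, unit), v in slopes.items()})
        table = pd.concat([table, pd.DataFrame(slope_rows, index=table.index)], axis=1)

    results = ExperimentResults(config=config, metrics=table, n_failed=n_failed)

    results.correlations = inference.species_interaction_correlation(table)

    reg_rows = []
    for net in ("PH", "HE", "PHE"):
        for predictor in (inference.DIET_PREDICTOR[net], f"richness_net_{net}",
                          f"abundance_net_{net}"):
            res = inference.residual_regression(table, net, predictor)
            reg_rows.append(dataclasses.asdict(res))
    results.residual_regressions = pd.DataFrame(reg_rows)

    if config.run_best:
        results.best = _best_comparisons(table, config)

    if config.run_path_model:
        results.path = inference.PathModel(table, FULL_PATH_EDGES).fit()

    if config.run_sweep:
        sequences = []
        kept_idx = []
        for i, (community, sub) in enumerate(zip(communities, streams)):
            if community.flags.get("no_herbivores"):
                continue
            rng = np.random.default_rng(sub[2])
            sequences.append(sample_community(community.table, rng))
            kept_idx.append(i)
        exo = table.loc[table.index[kept_idx], EXOGENOUS_COLS]
        results.sweep = inference.coefficient_sweep(
            sequences, exo, SWEEP_PATH_EDGES,
            sizes=config.sweep_sizes, min_webs=config.min_webs_per_size,
        )

    return results


def _best_comparisons(table: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Bayesian species-vs-interactions comparisons of Chao1 and slopes."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2**20 + 7)))
    rows = []
    quantities = [("chao1", "chao1_sp_{net}", "chao1_int_{net}")]
    if config.run_rarefaction:
        quantities.append(("slope", "slope_sp_{net}", "slope_int_{net}"))
    for net in ("PH", "HE", "PHE"):
        for qname, sp_tpl, int_tpl in quantities:
            sp_col = sp_tpl.format(net=net)
            int_col = int_tpl.format(net=net)
            if sp_col not in table or int_col not in table:
                continue
            sub = table[[sp_col, int_col]].dropna()
            if len(sub) < 2:
                continue
            res = inference.best_compare(
                sub[sp_col], sub[int_col],
                draws=config.best_draws, tune=config.best_tune,
                rng=rng, names=("species", "interactions"),
            )
            diff_lo, diff_hi = res.hdi(res.mean_diff)
            eff_lo, eff_hi = res.hdi(res.effect_size)
            rows.append({
                "network": net, "quantity": qname, "n": len(sub),
                "mean_species": float(np.mean(res.mu_a)),
                "mean_interactions": float(np.mean(res.mu_b)),
                "mean_diff": float(np.mean(res.mean_diff)),
                "hdi_diff_low": diff_lo, "hdi_diff_high": diff_hi,
                "effect_size": float(np.mean(res.effect_size)),
                "hdi_effect_low": eff_lo, "hdi_effect_high": eff_hi,
                "significant": bool(diff_lo > 0 or diff_hi < 0),
            })
    return pd.DataFrame(rows)
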