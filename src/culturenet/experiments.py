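"""End-to-end computational experiments on patterned cultures.

Each ``run_*`` function takes an :class:`ExperimentConfig`, builds the
substrates, grows networks, simulates activity and returns tidy pandas
tables.  Two parameter profiles are provided: the FULL profile
(r = 1.5 mm, ~2800 neurons, 600 s runs, 10 replicates — the model's
reference operating conditions) and a DESK profile (r = 0.75 mm, ~700
neurons, shorter runs, 3 replicates) for interactive work and routine
testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import gte as gte_mod, metrics
from .dynamics import DynamicsParams, simulate
from .growth import grow_network
from .topography import (
    ACTIVITY_CROSSING_TABLE,
    make_control,
    make_squares,
    make_tracks,
)

__all__ = [
    "ExperimentConfig",
    "DESK",
    "FULL",
    "make_substrate",
    "run_development_sweep",
    "fit_burst_size_model",
    "run_front_analysis",
    "run_richness_heatmap",
    "run_reconstruction",
    "run_calibration",
    "mann_whitney",
    "ks_test",
    "t_test",
]


@dataclass
class ExperimentConfig:
    """Shared knobs of a simulation campaign."""

    conditions: tuple = ("control", "tracks", "squares")
    culture_radius: float = 1.5        # mm
    density: float = 400.0             # neurons / mm^2
    mean_axon_lengths: tuple = (1.0,)  # <l> grid, mm
    heights: tuple = (0.1,)            # obstacle height grid, mm
    sigmas: tuple = (2.0,)             # noise intensity grid
    coverage: float = 0.25             # squares condition PDMS fraction
    replicates: int = 10
    duration: float = 600_000.0        # ms
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: full-size reference conditions used for the headline results
FULL = ExperimentConfig()
#: reduced problem size for interactive work and tests
DESK = ExperimentConfig(culture_radius=0.75, replicates=3, duration=120_000.0)


def make_substrate(condition: str, culture_radius: float, h: float,
                   rng=None, coverage: float = 0.25):
    """Build the obstacle map for a named condition."""
    if condition == "control":
        return make_control(culture_radius)
    if condition == "tracks":
        return make_tracks(culture_radius, h=h)
    if condition == "squares":
        return make_squares(culture_radius, coverage=coverage, h=h, rng=rng)
    raise ValueError(f"unknown condition {condition!r}")


def _grow_and_run(condition, cfg: ExperimentConfig, ell, h, sigma, rng):
    m = make_substrate(condition, cfg.culture_radius, h, rng, cfg.coverage)
    culture, net = grow_network(m, density=cfg.density,
                                mean_axon_length=ell, rng=rng)
    spikes = simulate(net, DynamicsParams(sigma=sigma), cfg.duration, rng=rng)
    return m, culture, net, spikes


def run_development_sweep(cfg: ExperimentConfig, theta_bins: int = 10):
    """Burst sizes and richness Theta across the axon-length grid.

    Returns ``(burst_df, theta_df)``: one row per detected burst
    (condition, ell, replicate, size) and one row per simulation run with
    its Theta.
    """
    rng = cfg.rng()
    burst_rows, theta_rows = [], []
    for condition in cfg.conditions:
        for ell in cfg.mean_axon_lengths:
            for rep in range(cfg.replicates):
                h = cfg.heights[0]
                _, _, _, spikes = _grow_and_run(
                    condition, cfg, ell, h, cfg.sigmas[0], rng)
                summary = metrics.analyze_activity(spikes)
                sizes = summary.peak_sizes
                for s in sizes:
                    burst_rows.append({"condition": condition, "ell": ell,
                                       "replicate": rep, "size": float(s)})
                theta_rows.append({
                    "condition": condition, "ell": ell, "replicate": rep,
                    "n_bursts": len(sizes),
                    "theta": metrics.dynamical_richness(sizes, theta_bins)
                    if len(sizes) else np.nan,
                })
    burst_df = pd.DataFrame(
        burst_rows, columns=["condition", "ell", "replicate", "size"])
    theta_df = pd.DataFrame(
        theta_rows, columns=["condition", "ell", "replicate", "n_bursts",
                             "theta"])
    return burst_df, theta_df


def fit_burst_size_model(burst_df: pd.DataFrame):
    """OLS of burst size on axon length, condition and their interaction.

    Returns a dict with the per-condition slope of size (fraction) per mm
    of ``<l>`` and the p-value of the joint interaction F-test (NaN when a
    single condition is fitted).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = burst_df.dropna(subset=["size"])
    conditions = sorted(df["condition"].unique())
    if df["ell"].nunique() < 2:
        raise ValueError("need at least two axon-length levels")
    if len(conditions) == 1:
        fit = smf.ols("size ~ ell", data=df).fit()
        return {"slopes": {conditions[0]: float(fit.params["ell"])},
                "interaction_p": float("nan"), "model": fit}
    fit = smf.ols("size ~ ell * C(condition)", data=df).fit()
    base = conditions[0]
    slopes = {base: float(fit.params["ell"])}
    for c in conditions[1:]:
        slopes[c] = float(fit.params["ell"]
                          + fit.params[f"ell:C(condition)[T.{c}]"])
    reduced = smf.ols("size ~ ell + C(condition)", data=df).fit()
    p = float(anova_lm(reduced, fit).iloc[1]["Pr(>F)"])
    return {"slopes": slopes, "interaction_p": p, "model": fit}


def run_front_analysis(cfg: ExperimentConfig):
    """Per-burst initiation points and front velocities over (h, sigma).

    Returns a long DataFrame with one row per burst; velocities on a
    tracks substrate are measured transverse to the stripes.
    """
    rng = cfg.rng()
    rows = []
    for condition in cfg.conditions:
        for h in cfg.heights:
            for sigma in cfg.sigmas:
                for rep in range(cfg.replicates):
                    m, culture, _, spikes = _grow_and_run(
                        condition, cfg, cfg.mean_axon_lengths[0], h, sigma, rng)
                    table = metrics.burst_table(spikes, culture.positions, m)
                    table["condition"] = condition
                    table["h"] = h
                    table["sigma"] = sigma
                    table["replicate"] = rep
                    rows.append(table)
    if not rows:
        return pd.DataFrame(columns=[
            "t_peak_ms", "size_frac", "n_participants", "x_init_mm",
            "y_init_mm", "velocity_mm_s", "condition", "h", "sigma",
            "replicate"])
    return pd.concat(rows, ignore_index=True)


def run_richness_heatmap(cfg: ExperimentConfig, condition: str = "tracks",
                         theta_bins: int = 10):
    """Mean Theta over replicates per (h, sigma) grid cell."""
    rng = cfg.rng()
    rows = []
    for h in cfg.heights:
        for sigma in cfg.sigmas:
            thetas = []
            for _ in range(cfg.replicates):
                _, _, _, spikes = _grow_and_run(
                    condition, cfg, cfg.mean_axon_lengths[0], h, sigma, rng)
                sizes = metrics.analyze_activity(spikes).peak_sizes
                if len(sizes):
                    thetas.append(metrics.dynamical_richness(sizes, theta_bins))
            rows.append({"h": h, "sigma": sigma,
                         "theta": float(np.mean(thetas)) if thetas else np.nan,
                         "n_runs": len(thetas)})
    return pd.DataFrame(rows)


def run_reconstruction(cfg: ExperimentConfig, condition: str = "tracks"):
    """GTE reconstruction AUC against the structural truth per (h, sigma)."""
    rng = cfg.rng()
    rows = []
    for h in cfg.heights:
        for sigma in cfg.sigmas:
            for rep in range(cfg.replicates):
                _, _, net, spikes = _grow_and_run(
                    condition, cfg, cfg.mean_axon_lengths[0], h, sigma, rng)
                eff = gte_mod.reconstruct(spikes)
                _, _, auc = gte_mod.roc_auc(eff.z, net)
                rows.append({"h": h, "sigma": sigma, "replicate": rep,
                             "auc": auc})
    return pd.DataFrame(rows)


def run_calibration(cfg: ExperimentConfig, heights=None, tolerance: float = 0.05,
                    **cal_kwargs):
    """Fit axon crossing probabilities to the activity targets per height."""
    rng = cfg.rng()
    heights = list(ACTIVITY_CROSSING_TABLE) if heights is None else heights
    rows = []
    for h in heights:
        targets = ACTIVITY_CROSSING_TABLE.get(h)
        if targets is None:
            raise ValueError(f"no activity targets for h={h}")
        (p_bt, p_tb), trail = metrics.calibrate_crossing_probabilities(
            targets, h, rng=rng, tolerance=tolerance,
            culture_radius=cal_kwargs.pop("culture_radius", cfg.culture_radius),
            density=cfg.density, duration=cfg.duration, **cal_kwargs)
        rows.append({"h": h,
                     "activity_bottom_to_top": targets[0],
                     "activity_top_to_bottom": targets[1],
                     "p_bottom_to_top": p_bt, "p_top_to_bottom": p_tb,
                     "n_iterations": len(trail)})
    return pd.DataFrame(rows)


# thin wrappers around the standard comparison tests used on summary tables
def mann_whitney(a, b, **kw):
    return _scipy_stats.mannwhitneyu(a, b, **kw)


def ks_test(a, b, **kw):
    return _scipy_stats.ks_2samp(a, b, **kw)


def t_test(a, b, **kw):
    return _scipy_stats.ttest_ind(a, b, **kw)
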