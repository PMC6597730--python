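"""Orchestrated in-silico experiments: dose-response sweeps and correlations.

A sweep maps each condition (substrate, inhibitor, ensemble size) through
the full chain: kinetics -> ground-truth speed -> ABP ensemble ->
(optionally render + track) -> per-particle MSD -> propulsive fit ->
ensemble speed summary, together with a simulated enzymatic-activity
readout. Everything is deterministic given the master seed: per-condition
seeds are derived from a stable hash of the condition label, so results do
not depend on condition order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .kinetics import ConditionSpec, KineticParams, measure_activity, relative_rate, speed_from_rate
from .msd import compute_msd, ensemble_msd, fit_propulsive, speed_summary
from .physics import RotationalScale, ThermalParams, translational_diffusion
from .presets import PRESETS
from .render import render_frames
from .simulate import add_localization_noise, simulate_ensemble
from .tracking import LinkingConfig, track_stack
from .trajectory import Trajectory

__all__ = [
    "CorrelationResult",
    "RunConfig",
    "condition_seed",
    "run_condition",
    "run_sweep",
    "correlate_speed_activity",
    "percent_speed_drop",
    "ensemble_propulsion_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Ordinary least-squares line speed ~ activity with adjusted R^2."""

    slope: float
    intercept: float
    r_squared_adj: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")
        if self.r_squared_adj > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


@dataclass
class RunConfig:
    """Everything a sweep needs, serializable to/from YAML.

    Acquisition defaults mirror the reference experimental design: 25 FPS,
    30 s recordings, 20 particles per condition, 1 um-radius spheres at
    24 degC in water-like solvent.
    """

    thermal: ThermalParams = field(default_factory=ThermalParams)
    kinetics: KineticParams = field(default_factory=lambda: PRESETS["urease"])
    conditions: list[ConditionSpec] = field(default_factory=list)
    fps: float = 25.0
    duration_s: float = 30.0
    substeps: int = 10
    localization_sigma_um: float = 0.03
    window_frac: float = 0.2
    activity_cv: float = 0.05
    # optional viscosity-vs-substrate hook: effective viscosity is
    # viscosity * (1 + slope * S_mM), modelling the alternative explanation
    # for speed decline at high substrate (thicker medium rather than
    # substrate inhibition); 0 disables
    viscosity_slope_per_mM: float = 0.0
    seed: int = 0
    # per-particle fits by default; "ensemble" fits the ensemble-mean MSD
    fit_mode: str = "per_particle"
    # image path (simulate -> render -> track) instead of direct trajectories
    image_path: bool = False
    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.2
    grid_spacing_um: float = 20.0
    max_disp_um: float = 0.7
    min_track_length: int | None = None

    def __post_init__(self) -> None:
        if self.fit_mode not in ("per_particle", "ensemble"):
            raise ValueError("fit_mode must be 'per_particle' or 'ensemble'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["kinetics"]["k_s_mM"] = (
            None if math.isinf(self.kinetics.k_s_mM) else self.kinetics.k_s_mM
        )
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "thermal" in d and isinstance(d["thermal"], dict):
            d["thermal"] = ThermalParams(**d["thermal"])
        kin = d.get("kinetics")
        if isinstance(kin, str):
            d["kinetics"] = PRESETS[kin]
        elif isinstance(kin, dict):
            kin = dict(kin)
            if kin.get("k_s_mM") is None:
                kin["k_s_mM"] = math.inf
            d["kinetics"] = KineticParams(**kin)
        d["conditions"] = [
            c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
            for c in d.get("conditions", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def condition_seed(master_seed: int, label: str) -> int:
    """Per-condition seed from the master seed and a stable label hash.

    CRC32 keeps the derivation independent of Python's randomized string
    hashing and of condition insertion order.
    """
    return (int(master_seed) + zlib.crc32(label.encode())) % (2**31)


def ensemble_propulsion_test(v_squared: list[float], alpha: float = 0.05) -> tuple[bool, float]:
    """One-sided test that the ensemble is propulsive.

    Per-particle fitted v^2 values are independent across particles and
    unbiased around the true v^2, so a one-sample t-test of mean(v^2) > 0
    is calibrated under the Brownian null. Returns (propulsive, p_value).
    """
    arr = np.asarray(v_squared, dtype=float)
    if arr.size < 2:
        return bool(arr.size and arr[0] > 0), float("nan")
    t_res = stats.ttest_1samp(arr, 0.0, alternative="greater")
    return bool(t_res.pvalue < alpha), float(t_res.pvalue)


def _grid_offsets(n: int, spacing: float, margin: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Square-grid start positions and the field-of-view side that fits them."""
    side = int(math.ceil(math.sqrt(n)))
    idx = np.arange(n)
    ox = margin + spacing * (idx % side)
    oy = margin + spacing * (idx // side)
    fov = 2 * margin + spacing * (side - 1)
    return ox, oy, fov


def run_condition(cfg: RunConfig, cond: ConditionSpec) -> dict[str, Any]:
    """Run one condition through the full chain; returns a result row."""
    seed = condition_seed(cfg.seed, cond.name)
    rng = np.random.default_rng(seed)
    rate = relative_rate(cond.substrate_mM, cond.inhibitor_mM, cfg.kinetics)
    v_true = speed_from_rate(rate, cfg.kinetics)
    activity = measure_activity(rate, rng, cv=cfg.activity_cv)

    thermal = cfg.thermal
    if cfg.viscosity_slope_per_mM:
        thermal = ThermalParams(
            radius_um=thermal.radius_um,
            temperature_K=thermal.temperature_K,
            viscosity_Pa_s=thermal.viscosity_Pa_s
            * (1.0 + cfg.viscosity_slope_per_mM * cond.substrate_mM),
        )
    d_t = translational_diffusion(thermal)
    rot = RotationalScale.from_thermal(thermal)

    trajs = simulate_ensemble(
        cond.n_particles,
        v=v_true,
        d_t=d_t,
        d_r=rot.d_r,
        fps=cfg.fps,
        duration=cfg.duration_s,
        seed=rng,
        substeps=cfg.substeps,
    )

    if cfg.image_path:
        margin = 0.6 * cfg.grid_spacing_um
        ox, oy, fov = _grid_offsets(cond.n_particles, cfg.grid_spacing_um, margin)
        shifted = [
            Trajectory(tr.particle_id, tr.times, tr.x + ox[i], tr.y + oy[i])
            for i, tr in enumerate(trajs)
        ]
        n_px = int(math.ceil(fov / cfg.pixel_size_um))
        stack = render_frames(
            shifted,
            shape_px=(n_px, n_px),
            pixel_size_um=cfg.pixel_size_um,
            psf_sigma_um=cfg.psf_sigma_um,
        )
        n_frames = len(trajs[0])
        min_len = cfg.min_track_length or max(n_frames // 2, 2)
        link_cfg = LinkingConfig(
            max_disp_um=cfg.max_disp_um, min_track_length=min_len, memory=1
        )
        analyzed = track_stack(stack, link_cfg, min_sep_um=2.0)
        if not analyzed:
            raise RuntimeError("tracking produced no usable trajectories")
    else:
        analyzed = [
            add_localization_noise(tr, cfg.localization_sigma_um, seed=rng) for tr in trajs
        ]

    max_lag = min(cfg.window_frac * rot.tau_r * 1.5, analyzed[0].duration)
    curves = [compute_msd(tr, max_lag=max_lag) for tr in analyzed]
    fits = [
        fit_propulsive(c, rot.tau_r, window_frac=cfg.window_frac, particle_id=tr.particle_id)
        for c, tr in zip(curves, analyzed)
    ]
    mean_v, sem_v = speed_summary(fits)
    propulsive, p_value = ensemble_propulsion_test([f.v_squared for f in fits])
    ens_fit = fit_propulsive(ensemble_msd(curves), rot.tau_r, window_frac=cfg.window_frac)
    return {
        "label": cond.name,
        "substrate_mM": cond.substrate_mM,
        "inhibitor_mM": cond.inhibitor_mM,
        "n_particles": cond.n_particles,
        "rate": rate,
        "activity": activity,
        "true_speed_um_s": v_true,
        "mean_v_um_s": mean_v,
        "sem_v_um_s": sem_v,
        "v_ensemble_um_s": ens_fit.v,
        "d_t_ensemble_um2_s": ens_fit.d_t,
        "propulsive": propulsive,
        "p_propulsion": p_value,
        "seed": seed,
    }


def run_sweep(cfg: RunConfig) -> pd.DataFrame:
    """Run every condition; failures are logged and skipped, not fatal.

    The returned table carries one row per successful condition (plus a
    ``label``-keyed error column for failed ones) and the primary speed
    estimate according to ``cfg.fit_mode``.
    """
    if not cfg.conditions:
        raise ValueError("config has no conditions")
    rows = []
    for cond in cfg.conditions:
        try:
            rows.append(run_condition(cfg, cond))
        except Exception as exc:  # noqa: BLE001 - stage failures must not kill the sweep
            logger.error("condition %r failed: %s", cond.name, exc)
            rows.append({"label": cond.name, "error": str(exc)})
    table = pd.DataFrame(rows)
    if cfg.fit_mode == "ensemble" and "v_ensemble_um_s" in table:
        table["v_um_s"] = table["v_ensemble_um_s"]
    elif "mean_v_um_s" in table:
        table["v_um_s"] = table["mean_v_um_s"]
    return table


def correlate_speed_activity(
    table: pd.DataFrame,
    speed_col: str = "v_um_s",
    activity_col: str = "activity",
) -> CorrelationResult:
    """OLS of condition-mean speed on condition activity, with adjusted R^2.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) for the single-predictor line.
    Raises on fewer than 3 finite points or zero activity variance.
    """
    sub = table[[speed_col, activity_col]].dropna()
    x = sub[activity_col].to_numpy(dtype=float)
    y = sub[speed_col].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 conditions with finite speed and activity")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("activity has zero variance; correlation undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return CorrelationResult(
        slope=float(res.slope), intercept=float(res.intercept), r_squared_adj=float(r2_adj), n=n
    )


def percent_speed_drop(
    table: pd.DataFrame,
    reference_label: str,
    speed_col: str = "v_um_s",
) -> pd.Series:
    """Percent speed decrease of every condition relative to a reference.

    100 * (1 - v / v_ref); negative values mean speed-up. Raises if the
    reference condition is missing or has zero (or negative) speed.
    """
    ref_rows = table.loc[table["label"] == reference_label, speed_col]
    if ref_rows.empty:
        raise ValueError(f"reference condition {reference_label!r} not in table")
    v_ref = float(ref_rows.iloc[0])
    if not v_ref > 0:
        raise ValueError("reference speed must be > 0")
    return pd.Series(
        100.0 * (1.0 - table[speed_col] / v_ref), index=table.index, name="speed_drop_pct"
    )
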