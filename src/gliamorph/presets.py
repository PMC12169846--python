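"""Condition presets and their calibration to target effect sizes.

The simulated study encodes the group contrasts reported for developing
hypothalamic microglia: at P16 in the PVH, maternal high-fat diet during
lactation (MHFD-L) increases Sholl branching complexity by 44% and total
process length by 87% and roughly doubles cell volume and territory; in the
ARH, process length grows 67% from P16 to P30 under normal chow; in the
BST, AgRP-terminal density rises 61% from P16 to P30; microglial density
halves from P16 to P30 in all three regions.

Calibration is a deterministic 1-D bisection on the single morphology
parameter that governs each statistic: segment length for total process
length (ground-truth length is exactly linear in it), direction-diffusion
rate (tortuosity) for Sholl AUC at fixed length, and spot density for
terminal density (where the statistic is the parameter).  Ground-truth
statistics are evaluated on paired seeds, so realized ratios converge
tightly at modest replicate counts.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Mapping, Optional

import numpy as np

from .growth import MorphologyParams, grow_cell
from .render import ScenePreset

__all__ = ["DEFAULT_TARGETS", "calibrate_presets", "default_presets"]

# printed percent changes the presets reproduce
DEFAULT_TARGETS: dict[str, float] = {
    "pvh_p16_length": 87.0,       # MHFD-L vs NCD, PVH P16
    "pvh_p16_sholl": 44.0,        # MHFD-L vs NCD, PVH P16, Sholl complexity
    "arh_length": 67.0,           # NCD P30 vs P16, ARH
    "bst_terminal_density": 61.0  # P30 vs P16, BST AgRP terminals
}

_BOUNDS = {
    "segment_length_mean": (0.25, 4.0),   # relative to the base value
    "tortuosity": (0.02, 2.5),            # absolute
}

_DENSITY_P16 = 4000.0   # cells/mm³; halves by P30 in every region
_VOLUME_TARGET = 2.0    # PVH-P16 cell-volume ratio under MHFD-L ("nearly doubled")


class CalibrationError(ValueError):
    pass


def _search(
    fn: Callable[[float], float],
    lo: float,
    hi: float,
    target: float,
    param: str,
    tol: float = 0.05,
    increasing: bool = True,
    max_iter: int = 60,
) -> float:
    """Deterministic bisection of a monotone statistic; errors at a bound."""
    f_lo, f_hi = fn(lo), fn(hi)
    if not increasing:
        lo, hi, f_lo, f_hi = hi, lo, f_hi, f_lo
    if target < min(f_lo, f_hi) or target > max(f_lo, f_hi):
        at = param + (" at its lower bound" if target < min(f_lo, f_hi) else " at its upper bound")
        raise CalibrationError(
            f"target {target:.3g} unreachable within bounds of {at} "
            f"(reachable range [{min(f_lo, f_hi):.3g}, {max(f_lo, f_hi):.3g}])"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fn(mid)
        if abs(f_mid / target - 1.0) <= tol and abs(hi - lo) <= 0.02 * abs(mid):
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mean_length(params: MorphologyParams, seeds) -> float:
    return float(np.mean([grow_cell(params, s).generative_length for s in seeds]))


def _mean_auc(params: MorphologyParams, seeds, step: float = 1.0) -> float:
    from .morphometry import sholl

    return float(np.mean([sholl(grow_cell(params, s), step).summary_auc for s in seeds]))


def calibrate_presets(
    targets: Optional[Mapping[str, float]] = None,
    n_reps: int = 48,
    seed: int = 0,
    tol: float = 0.05,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> dict[str, ScenePreset]:
    """Build the condition presets, calibrated so the ground-truth population
    statistics reproduce ``targets`` (percent changes) within ``tol`` relative.

    ``bounds`` overrides the default search bounds (keyed by morphology
    parameter; ``segment_length_mean`` bounds are relative to the base
    value).  An unreachable target raises :class:`CalibrationError` naming
    the parameter at its bound.
    """
    targets = dict(DEFAULT_TARGETS if targets is None else targets)
    for k, v in targets.items():
        if not np.isfinite(v) or v <= -100.0:
            raise ValueError(f"target {k}={v} must be finite and > -100%")
    search_bounds = dict(_BOUNDS)
    if bounds:
        search_bounds.update(bounds)

    base = MorphologyParams()
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF]
    base_len = _mean_length(base, seeds)
    base_auc = _mean_auc(base, seeds)

    # --- PVH P16: MHFD-L morphology -------------------------------------
    mhfd = base
    t_len = targets.get("pvh_p16_length", 0.0)
    if t_len != 0.0:
        lo, hi = search_bounds["segment_length_mean"]
        m = _search(
            lambda v: _mean_length(base.replace(segment_length_mean=v), seeds) / base_len,
            lo * base.segment_length_mean,
            hi * base.segment_length_mean,
            1.0 + t_len / 100.0,
            "segment_length_mean",
            tol=tol,
        )
        mhfd = mhfd.replace(segment_length_mean=m)
    t_auc = targets.get("pvh_p16_sholl", 0.0)
    if t_auc != 0.0:
        lo, hi = search_bounds["tortuosity"]
        tau = _search(
            lambda v: _mean_auc(mhfd.replace(tortuosity=v), seeds) / base_auc,
            lo,
            hi,
            1.0 + t_auc / 100.0,
            "tortuosity",
            tol=tol,
            increasing=False,
        )
        mhfd = mhfd.replace(tortuosity=tau)
    if t_len != 0.0 or t_auc != 0.0:
        # cell volume ≈ soma + π r² L: bump the tube radius so volume doubles
        len_ratio = 1.0 + t_len / 100.0
        mhfd = mhfd.replace(
            process_radius=base.process_radius * float(np.sqrt(_VOLUME_TARGET / len_ratio))
        )

    # --- ARH: P30 NCD morphology -----------------------------------------
    arh_p30_m = base.replace(tortuosity=0.3)
    t_arh = targets.get("arh_length", 0.0)
    if t_arh != 0.0:
        lo, hi = search_bounds["segment_length_mean"]
        m = _search(
            lambda v: _mean_length(arh_p30_m.replace(segment_length_mean=v), seeds) / base_len,
            lo * base.segment_length_mean,
            hi * base.segment_length_mean,
            1.0 + t_arh / 100.0,
            "segment_length_mean",
            tol=tol,
        )
        arh_p30_m = arh_p30_m.replace(segment_length_mean=m)

    # --- BST: terminal density (the statistic is the parameter) -----------
    bst_p16_spots = 1.6
    bst_p30_spots = bst_p16_spots * (1.0 + targets.get("bst_terminal_density", 0.0) / 100.0)

    p16 = dict(cell_density=_DENSITY_P16, contact_fraction=0.12, engulfed_fraction=0.05,
               cd68_volume_per_cell=30.0)
    p30 = dict(cell_density=_DENSITY_P16 / 2, contact_fraction=0.10, engulfed_fraction=0.03,
               cd68_volume_per_cell=15.0)

    presets = {
        "pvh_p16_ncd": ScenePreset(name="pvh_p16_ncd", morphology=base, spot_density=1.2, **p16),
        "pvh_p16_mhfd": ScenePreset(name="pvh_p16_mhfd", morphology=mhfd, spot_density=0.8, **p16),
        "pvh_p30_ncd": ScenePreset(name="pvh_p30_ncd", morphology=base, spot_density=1.2, **p30),
        "pvh_p30_mhfd": ScenePreset(name="pvh_p30_mhfd", morphology=base, spot_density=0.8, **p30),
        "arh_p16_ncd": ScenePreset(name="arh_p16_ncd", morphology=base, spot_density=1.0, **p16),
        "arh_p30_ncd": ScenePreset(name="arh_p30_ncd", morphology=arh_p30_m, spot_density=1.0, **p30),
        "bst_p16": ScenePreset(name="bst_p16", morphology=base, spot_density=bst_p16_spots,
                               contact_fraction=0.10, engulfed_fraction=0.04,
                               cell_density=_DENSITY_P16, cd68_volume_per_cell=20.0),
        "bst_p30": ScenePreset(name="bst_p30", morphology=base, spot_density=bst_p30_spots,
                               contact_fraction=0.10, engulfed_fraction=0.04,
                               cell_density=_DENSITY_P16 / 2, cd68_volume_per_cell=20.0),
    }
    return presets


@lru_cache(maxsize=4)
def default_presets(n_reps: int = 48, seed: int = 0) -> dict[str, ScenePreset]:
    """Presets calibrated to the study's printed effect sizes (cached)."""
    return calibrate_presets(DEFAULT_TARGETS, n_reps=n_reps, seed=seed)
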