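"""Trajectory observables: profiles, region partition, densities, strain,
friction curves and scaling fits.

Conventions: distances are reported as z/xi0, gel density as rho_g/rho0,
solvent velocity as v/V and friction as mu/mu0 where mu0 is the mean
friction coefficient in the Wi-independent (thermal) regime Wi < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProfileSet",
    "RegionPartition",
    "GelMetrics",
    "ScalingFit",
    "density_profile",
    "velocity_profile",
    "partition_regions",
    "region_densities",
    "shear_strain",
    "friction_curves",
    "fit_scaling",
]

MU0_WI_WINDOW = 0.01  # Wi below this is the thermal, Wi-independent regime


@dataclass
class ProfileSet:
    """A z-binned profile with sample bookkeeping."""

    z: np.ndarray          # bin centres
    value: np.ndarray      # rho_g/rho0 or <v_x> (normalized by V if given)
    counts: np.ndarray     # samples per bin
    bin_width: float
    kind: str              # "density" | "velocity"
    normalization: float   # rho0 or V (1.0 if unnormalized)


def _frames_z(frames, mask):
    for f in frames:
        pos = f.pos if hasattr(f, "pos") else np.asarray(f)
        yield pos[mask] if mask is not None else pos


def density_profile(frames, species_mask, box, *, rho0: float = 3.0,
                    nbins: int | None = None, bin_width: float | None = None,
                    zmax: float | None = None) -> ProfileSet:
    """Time-averaged bead density per z-bin, normalized by rho0.

    ``frames`` is an iterable of (N, 3) position arrays (or objects with a
    ``.pos``); ``species_mask`` selects the species to bin (None = all).
    """
    Lx, Ly, Lz = box
    zmax = zmax if zmax is not None else Lz
    if nbins is None:
        bw = bin_width if bin_width is not None else 0.32
        nbins = max(int(round(zmax / bw)), 1)
    if nbins < 1 or zmax <= 0:
        raise ValueError("empty bin range")
    edges = np.linspace(0.0, zmax, nbins + 1)
    counts = np.zeros(nbins)
    n_frames = 0
    for pos in _frames_z(frames, species_mask):
        z = np.clip(pos[:, 2], 0, zmax - 1e-9)
        counts += np.bincount((z / (zmax / nbins)).astype(np.int64),
                              minlength=nbins)[:nbins]
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no frames")
    bin_vol = Lx * Ly * (zmax / nbins)
    dens = counts / n_frames / bin_vol
    centers = 0.5 * (edges[1:] + edges[:-1])
    return ProfileSet(centers, dens / rho0, counts, zmax / nbins,
                      "density", rho0)


def profile_from_accumulator(acc, box, *, rho0: float = 3.0, V: float = 0.0):
    """Convert a ShearCell ProfileAccumulator into (density, velocity)
    ProfileSets."""
    Lx, Ly, Lz = box
    nb = len(acc.gel_count)
    bw = acc.edges[-1] / nb
    centers = 0.5 * (acc.edges[1:] + acc.edges[:-1])
    bin_vol = Lx * Ly * bw
    dens = acc.gel_count / max(acc.n_frames, 1) / bin_vol / rho0
    dprof = ProfileSet(centers, dens, acc.gel_count, bw, "density", rho0)
    with np.errstate(invalid="ignore"):
        v = np.where(acc.sol_count > 0, acc.sol_vx / np.maximum(acc.sol_count, 1),
                     np.nan)
    norm = V if V != 0.0 else 1.0
    vprof = ProfileSet(centers, v / norm, acc.sol_count, bw, "velocity", norm)
    return dprof, vprof


def velocity_profile(frames_pos, frames_vel, species_mask, box, *,
                     V: float = 0.0, nbins: int = 50) -> ProfileSet:
    """Time-averaged mean x-velocity per z-bin, normalized by V when
    sliding (V=0 returns the unnormalized profile)."""
    Lx, Ly, Lz = box
    edges = np.linspace(0.0, Lz, nbins + 1)
    vsum = np.zeros(nbins)
    cnt = np.zeros(nbins)
    for pos, vel in zip(frames_pos, frames_vel):
        p = pos[species_mask] if species_mask is not None else pos
        v = vel[species_mask] if species_mask is not None else vel
        z = np.clip(p[:, 2], 0, Lz - 1e-9)
        idx = (z / (Lz / nbins)).astype(np.int64)
        vsum += np.bincount(idx, weights=v[:, 0], minlength=nbins)
        cnt += np.bincount(idx, minlength=nbins)
    with np.errstate(invalid="ignore"):
        prof = np.where(cnt > 0, vsum / np.maximum(cnt, 1), np.nan)
    norm = V if V != 0.0 else 1.0
    centers = 0.5 * (edges[1:] + edges[:-1])
    return ProfileSet(centers, prof / norm, cnt, Lz / nbins, "velocity", norm)


@dataclass
class RegionPartition:
    """Interface [0, 0.3 xi0], transition (0.3 xi0, z_t], bulk above z_t."""

    xi0: float
    z_interface: float
    z_t: float
    gel_top: float

    def __post_init__(self) -> None:
        if not 0 < self.z_interface < self.z_t < self.gel_top:
            raise ValueError("inconsistent region boundaries")


def partition_regions(profile: ProfileSet, xi0: float, *,
                      plateau_threshold: float = 0.95) -> RegionPartition:
    """Partition a gel density profile into interface/transition/bulk.

    The interface band is fixed at [0, 0.3 xi0].  The bulk plateau is the
    mean density over the central half of the gel extent, and the
    transition edge z_t is the smallest z where the profile first reaches
    ``plateau_threshold`` of the plateau.
    """
    z, rho = profile.z, profile.value
    occupied = np.flatnonzero(rho > 0.02)
    if occupied.size == 0:
        raise ValueError("no gel in profile")
    gel_top = z[occupied[-1]]
    if gel_top < 4 * xi0:
        raise ValueError("gel thinner than 4 mesh sizes: no resolvable "
                         "plateau")
    central = (z > 0.25 * gel_top) & (z < 0.75 * gel_top)
    plateau = float(rho[central].mean())
    thresh = plateau_threshold * plateau
    above = np.flatnonzero((rho >= thresh) & (z <= 0.75 * gel_top))
    if above.size == 0:
        raise ValueError("profile never reaches the plateau")
    z_t = float(z[above[0]])
    z_t = max(z_t, 0.3 * xi0 + profile.bin_width)
    return RegionPartition(xi0, 0.3 * xi0, z_t, float(gel_top))


def region_densities(profile: ProfileSet, partition: RegionPartition):
    """(rho_b/rho0, rho_i/rho0): bulk mean above z_t (up to 0.75 gel top)
    and interface mean over [0, 0.3 xi0]."""
    z, rho = profile.z, profile.value
    bulk = (z >= partition.z_t) & (z <= 0.75 * partition.gel_top)
    iface = z <= partition.z_interface
    if not bulk.any() or not iface.any():
        raise ValueError("empty region")
    return float(rho[bulk].mean()), float(rho[iface].mean())


def shear_strain(disp_x: np.ndarray, z_ref: np.ndarray,
                 drift_ids=None) -> float:
    """Shear strain gamma from the mean lateral displacement field.

    gamma is the slope of the x-displacement (relative to the unloaded
    reference configuration, rigid drift removed) against the reference
    height z: the tangent of the tilt of initially vertical material
    lines.  ``drift_ids`` optionally names the bead set whose mean motion
    defines the rigid drift (e.g. the tethered top layer); the slope is
    unaffected by any constant offset, so this only recentres.
    """
    if len(disp_x) != len(z_ref):
        raise ValueError("reference configuration mismatch")
    d = np.asarray(disp_x, dtype=float)
    if drift_ids is not None:
        d = d - d[drift_ids].mean()
    A = np.vstack([z_ref, np.ones_like(z_ref)]).T
    slope, _ = np.linalg.lstsq(A, d, rcond=None)[0]
    return float(slope)


@dataclass
class GelMetrics:
    rho_b: float
    rho_i: float
    gamma: float
    rho_b_err: float = 0.0
    rho_i_err: float = 0.0
    gamma_err: float = 0.0


def friction_curves(records) -> pd.DataFrame:
    """Collate friction records into mu(Wi; P) with mu0 normalization.

    mu0 is, per load P, the mean mu over runs in the thermal window
    Wi < 0.01; if a load has no such runs the normalized column is NaN for
    it (with a warning).
    """
    import warnings

    rows = [{"Wi": r.Wi, "P": r.P, "mu": r.mu, "mu_err": r.mu_err,
             "seed": r.seed} for r in records]
    df = pd.DataFrame(rows).sort_values(["P", "Wi"]).reset_index(drop=True)
    mu0 = {}
    for P, g in df.groupby("P"):
        low = g[g.Wi < MU0_WI_WINDOW]
        if len(low):
            mu0[P] = low.mu.mean()
        else:
            warnings.warn(f"no Wi<{MU0_WI_WINDOW} runs at P={P}; "
                          "normalization skipped")
            mu0[P] = np.nan
    df["mu0"] = df.P.map(mu0)
    df["mu_norm"] = df.mu / df.mu0
    return df


@dataclass
class ScalingFit:
    """Weighted least-squares linear or power-law fit."""

    kind: str
    slope: float           # slope (linear) or exponent (power)
    slope_err: float
    intercept: float
    n_points: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.intercept + self.slope * x
        return np.exp(self.intercept) * x ** self.slope


def fit_scaling(x, y, yerr=None, kind: str = "linear", *,
                n_boot: int = 0, seed: int = 0) -> ScalingFit:
    """Fit y = a + b x (linear) or y = c x^b (power law, via log-log WLS).

    Errors are propagated into weights; the slope/exponent standard error
    comes from the WLS covariance, or from a bootstrap when ``n_boot`` > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if yerr is None:
        w = np.ones_like(y)
    else:
        w = 1.0 / np.clip(np.asarray(yerr, dtype=float), 1e-12, None)
    if kind == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power-law fit requires positive data")
        w = w * y  # d(log y) = dy / y
        X, Y = np.log(x), np.log(y)
    elif kind == "linear":
        X, Y = x, y
    else:
        raise ValueError(f"unknown fit kind {kind!r}")
    coef, cov = np.polyfit(X, Y, 1, w=w, cov="unscaled")
    slope, intercept = float(coef[0]), float(coef[1])
    if n_boot:
        rng = np.random.default_rng(seed)
        bs = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(X), len(X))
            if len(np.unique(X[idx])) < 2:
                continue
            bs.append(np.polyfit(X[idx], Y[idx], 1, w=w[idx])[0])
        err = float(np.std(bs))
    else:
        err = float(np.sqrt(cov[0, 0]))
        if yerr is None and len(X) > 2:
            resid = Y - (intercept + slope * X)
            err = float(err * np.sqrt(np.sum((w * resid) ** 2)
                                      / (len(X) - 2)))
    return ScalingFit(kind, slope, err, intercept, len(x))
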