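"""Periodic-image and conformational artifact diagnostics.

A solute in a periodic box interacts with its own images; when the buffer
of solvent between images is thin, conformational ensembles get biased
(extended states overstabilized, orientations locked to the box faces).
This module provides the observables used to detect that: the minimal
distance to the box wall (half the minimal self-image distance),
end-to-end free-energy profiles with replica confidence intervals, basin
free-energy differences, orientation maps on an equal-area sphere
partition, and the per-box-size comparison against the largest box.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import K_BOLTZMANN, T_DEFAULT

__all__ = [
    "FreeEnergyProfile",
    "BasinComparison",
    "BoxSeriesReport",
    "min_image_self_distance",
    "wall_distance_summary",
    "end_to_end",
    "free_energy_profile",
    "basin_delta_g",
    "orientation_map",
    "box_series",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class FreeEnergyProfile:
    """Binned free energy over a distance coordinate, replica-resolved."""

    bin_centers: np.ndarray  # nm
    dg_mean: np.ndarray  # kJ/mol, anchored so min over bins = 0
    ci95: np.ndarray  # kJ/mol
    dg_replicas: np.ndarray  # (n_replicas, n_bins), NaN for empty bins
    n_replicas: int
    temperature: float

    def to_dict(self) -> dict:
        def clean(a):
            return [None if not np.isfinite(v) else float(v) for v in a]

        return {
            "bin_centers_nm": [float(v) for v in self.bin_centers],
            "dG_kJ_mol": clean(self.dg_mean),
            "ci95_kJ_mol": clean(self.ci95),
            "n_replicas": self.n_replicas,
            "temperature_K": self.temperature,
        }


@dataclass
class BasinComparison:
    """Free-energy difference between two distance windows."""

    range_a: tuple[float, float]
    range_b: tuple[float, float]
    counts_a: list[int]
    counts_b: list[int]
    dg_ab: float  # kJ/mol, mean over replicas
    ci95: float
    dg_replicas: list[float] = field(default_factory=list)
    excluded_replicas: list[int] = field(default_factory=list)
    significant: bool | None = None

    def to_dict(self) -> dict:
        return {
            "range_A_nm": list(self.range_a),
            "range_B_nm": list(self.range_b),
            "counts_A": self.counts_a,
            "counts_B": self.counts_b,
            "dG_AB_kJ_mol": self.dg_ab,
            "ci95_kJ_mol": self.ci95,
            "excluded_replicas": self.excluded_replicas,
            "significant": self.significant,
        }


@dataclass
class BoxSeriesReport:
    """An observable across box sizes, referenced to the largest box."""

    box_edges: list[float]
    values: list[float]
    differences: list[float]  # value(box) - value(largest)
    ci95: list[float]
    significant: list[bool]
    has_ci: bool = True

    def to_dict(self) -> dict:
        return {
            "box_edges_nm": self.box_edges,
            "values": self.values,
            "difference_to_largest": self.differences,
            "ci95": self.ci95,
            "significant": self.significant,
            "has_ci": self.has_ci,
        }


_NEIGHBOR_SHIFTS = np.array(
    [v for v in itertools.product((-1, 0, 1), repeat=3) if v != (0, 0, 0)],
    dtype=float,
)


def min_image_self_distance(positions: np.ndarray, box_edge: float) -> float:
    """Minimal distance to the box wall: half the minimal distance between
    any atom and any atom of the molecule's periodic images.

    The minimum runs over all atom pairs (i, j), including i == j, and the
    26 nonzero neighbor translations n L.  Returns 0 with a warning when
    the molecule overlaps its own image (extent >= L).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("need at least one atom")
    if len(pos) > 1 and np.any(pos.max(axis=0) - pos.min(axis=0) >= box_edge):
        warnings.warn("molecule overlaps its periodic image (extent >= L)")
        return 0.0
    best = np.inf
    diff = pos[:, None, :] - pos[None, :, :]  # (n, n, 3)
    for shift in _NEIGHBOR_SHIFTS:
        d = diff - box_edge * shift
        r2 = np.einsum("ijk,ijk->ij", d, d)
        best = min(best, float(np.sqrt(r2.min())))
    if best <= 0.0:
        warnings.warn("molecule overlaps its periodic image (extent >= L)")
        return 0.0
    return 0.5 * best


def wall_distance_summary(
    trajectories: list[list[np.ndarray]], box_edge: float
) -> dict:
    """{init, avg, min} of the minimal wall distance over replica series.

    ``init`` is the value on the first frame of the first replica (the
    starting structure); ``avg`` the mean of per-frame values over all
    frames of all replicas; ``min`` the global minimum.
    """
    if not trajectories or not trajectories[0]:
        raise ValueError("need at least one replica with at least one frame")
    values = [
        min_image_self_distance(frame, box_edge)
        for replica in trajectories
        for frame in replica
    ]
    return {
        "init_nm": float(
            min_image_self_distance(trajectories[0][0], box_edge)
        ),
        "avg_nm": float(np.mean(values)),
        "min_nm": float(np.min(values)),
        "n_frames": len(values),
    }


def end_to_end(frame: np.ndarray, n_index: int, c_index: int) -> float:
    """Euclidean end-to-end distance between two atoms of an intact
    molecule (no periodic wrapping), in nm."""
    pos = np.asarray(frame, dtype=float).reshape(-1, 3)
    return float(np.linalg.norm(pos[n_index] - pos[c_index]))


def free_energy_profile(
    distances: list[np.ndarray],
    bins: np.ndarray | int = 50,
    temperature: float = T_DEFAULT,
    bin_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Free-energy profile -kT ln h(d) from replica distance samples.

    Each replica is histogrammed separately; empty bins are absent values
    (NaN), not zero.  The mean profile is anchored so its minimum is zero
    and the 95% CI per bin is 1.96 times the standard error over replicas.
    """
    if len(distances) < 2:
        raise ValueError("need >= 2 replicas for a confidence interval")
    all_d = np.concatenate([np.asarray(d, dtype=float) for d in distances])
    if all_d.size == 0:
        raise ValueError("no samples")
    if isinstance(bins, int):
        lo, hi = bin_range if bin_range is not None else (all_d.min(), all_d.max())
        edges = np.linspace(lo, hi, bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = K_BOLTZMANN * temperature

    prof = np.full((len(distances), len(centers)), np.nan)
    for r, d in enumerate(distances):
        h, _ = np.histogram(np.asarray(d, dtype=float), bins=edges)
        frac = h / max(len(d), 1)
        occupied = h > 0
        prof[r, occupied] = -kt * np.log(frac[occupied])
        prof[r] -= np.nanmin(prof[r]) if occupied.any() else 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(prof, axis=0)
        n_eff = np.sum(np.isfinite(prof), axis=0)
        sd = np.nanstd(prof, axis=0, ddof=1)
    ci = np.where(n_eff > 1, _Z95 * sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    if not np.any(np.isfinite(mean)):
        raise ValueError("all histogram bins are empty")
    mean = mean - np.nanmin(mean)
    return FreeEnergyProfile(
        bin_centers=centers,
        dg_mean=mean,
        ci95=ci,
        dg_replicas=prof,
        n_replicas=len(distances),
        temperature=temperature,
    )


def basin_delta_g(
    distances: list[np.ndarray],
    range_a: tuple[float, float],
    range_b: tuple[float, float],
    temperature: float = T_DEFAULT,
    reference: "BasinComparison | None" = None,
) -> BasinComparison:
    """dG_AB = -kT ln(N_A / N_B) from conformer counts in two windows.

    Positive values mean basin A is less populated than basin B.  Replicas
    with a zero count in either window are excluded with a warning.  When
    ``reference`` is given, significance is judged by whether zero falls
    outside the 95% CI of the difference to the reference.
    """
    a_lo, a_hi = range_a
    b_lo, b_hi = range_b
    if max(a_lo, b_lo) < min(a_hi, b_hi):
        raise ValueError("basin windows must be disjoint")
    kt = K_BOLTZMANN * temperature
    counts_a, counts_b, dgs, excluded = [], [], [], []
    for r, d in enumerate(distances):
        d = np.asarray(d, dtype=float)
        na = int(np.sum((d >= a_lo) & (d < a_hi)))
        nb = int(np.sum((d >= b_lo) & (d < b_hi)))
        counts_a.append(na)
        counts_b.append(nb)
        if na == 0 or nb == 0:
            warnings.warn(f"replica {r} has an empty basin window; excluded")
            excluded.append(r)
            continue
        dgs.append(-kt * np.log(na / nb))
    if not dgs:
        raise ValueError("no replica has nonzero counts in both windows")
    dgs = np.asarray(dgs)
    ci = float(_Z95 * dgs.std(ddof=1) / np.sqrt(len(dgs))) if len(dgs) > 1 else 0.0
    result = BasinComparison(
        range_a=range_a,
        range_b=range_b,
        counts_a=counts_a,
        counts_b=counts_b,
        dg_ab=float(dgs.mean()),
        ci95=ci,
        dg_replicas=[float(v) for v in dgs],
        excluded_replicas=excluded,
    )
    if reference is not None:
        diff = result.dg_ab - reference.dg_ab
        ci_diff = float(np.hypot(result.ci95, reference.ci95))
        result.significant = abs(diff) > ci_diff
    return result


def equal_area_bins(n_theta: int = 6, n_phi: int = 12):
    """Equal-area sphere partition: uniform bands in cos(theta) crossed
    with uniform phi slices.  Every bin covers the same solid angle."""
    z_edges = np.linspace(1.0, -1.0, n_theta + 1)
    phi_edges = np.linspace(-np.pi, np.pi, n_phi + 1)
    return z_edges, phi_edges


def orientation_map(
    vectors: np.ndarray,
    n_theta: int = 6,
    n_phi: int = 12,
    face_radius_deg: float = 20.0,
) -> dict:
    """Histogram of orientations on an equal-area sphere partition.

    ``vectors`` are (n, 3) direction vectors (need not be normalized;
    zero-length vectors are skipped with a warning).  Also reports the
    face-alignment score: the fraction of samples within ``face_radius_deg``
    of any of the six axis directions +-x, +-y, +-z, together with the
    solid-angle fraction an isotropic ensemble would give.
    """
    v = np.asarray(vectors, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(v, axis=1)
    bad = norms < 1e-12
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-length vectors skipped")
        v, norms = v[~bad], norms[~bad]
    if len(v) == 0:
        raise ValueError("no usable orientation vectors")
    u = v / norms[:, None]
    z = np.clip(u[:, 2], -1.0, 1.0)
    phi = np.arctan2(u[:, 1], u[:, 0])
    z_edges, phi_edges = equal_area_bins(n_theta, n_phi)
    # z_edges descend from +1 to -1; histogram2d needs ascending edges
    iz = np.clip(np.searchsorted(-z_edges, -z, side="right") - 1, 0, n_theta - 1)
    ip = np.clip(np.searchsorted(phi_edges, phi, side="right") - 1, 0, n_phi - 1)
    counts = np.zeros((n_theta, n_phi), dtype=int)
    np.add.at(counts, (iz, ip), 1)

    rho = np.deg2rad(face_radius_deg)
    cos_rho = np.cos(rho)
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    aligned = np.any(u @ axes.T >= cos_rho, axis=1)
    score = float(aligned.mean())
    iso_expect = min(1.0, 6.0 * (1.0 - cos_rho) / 2.0)  # six disjoint caps
    return {
        "counts": counts,
        "n_samples": int(len(u)),
        "z_edges": z_edges,
        "phi_edges": phi_edges,
        "face_alignment_score": score,
        "isotropic_expectation": iso_expect,
        "face_radius_deg": face_radius_deg,
    }


def box_series(
    box_edges: list[float],
    replica_values: list[np.ndarray],
) -> BoxSeriesReport:
    """Observable vs box size, differenced against the largest box.

    Per box, the observable is the replica mean; the difference to the
    largest box carries a 95% CI from the combined standard errors
    (normal approximation), and boxes whose CI excludes zero are flagged
    significant.  Single-replica input yields differences without CIs.
    """
    if len(box_edges) < 2:
        raise ValueError("need at least two box sizes")
    if len(box_edges) != len(replica_values):
        raise ValueError("one replica-value array per box is required")
    order = np.argsort(box_edges)
    edges = [float(box_edges[i]) for i in order]
    vals = [np.atleast_1d(np.asarray(replica_values[i], float)) for i in order]
    means = [float(v.mean()) for v in vals]
    ses = [
        float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        for v in vals
    ]
    has_ci = all(np.isfinite(s) for s in ses)
    ref_mean, ref_se = means[-1], ses[-1]
    diffs, cis, sig = [], [], []
    for i, (m, s) in enumerate(zip(means, ses)):
        if i == len(means) - 1:
            diffs.append(0.0)
            cis.append(0.0)
            sig.append(False)
            continue
        d = m - ref_mean
        diffs.append(d)
        if has_ci:
            ci = _Z95 * float(np.hypot(s, ref_se))
            cis.append(ci)
            sig.append(abs(d) > ci)
        else:
            cis.append(float("nan"))
            sig.append(False)
    return BoxSeriesReport(
        box_edges=edges,
        values=means,
        differences=diffs,
        ci95=cis,
        significant=sig,
        has_ci=has_ci,
    )
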