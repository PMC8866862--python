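"""Healing-region strain and device stress statistics.

At every element integration point the principal strains of the healing
(granulation) region are computed and reduced to the dominant principal
strain: whichever of the maximum and minimum principal strains is larger in
absolute value, keeping its sign (positive = prevailing tension, negative =
prevailing compression; exact ties count as tensile).  Strains are reported
in percent; the interfragmentary-strain criterion flags the fraction of
points below 15% magnitude, the level under which bone formation is expected.

Device assessment uses von Mises stress at the integration points of plate
and screw elements.  To suppress constraint-induced stress singularities the
top 0.1% of values are excluded and the peak is the mean of the 10 highest
remaining values; the yield ratio is peak / yield strength of the device
material (880 MPa Ti-6Al-4V, 162 MPa WE43, 70 MPa PLA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PostprocessError(ValueError):
    pass


def _to_tensor(voigt: np.ndarray, shear_factor: float) -> np.ndarray:
    """(..., 6) Voigt (11,22,33,12,13,23) -> (..., 3, 3) symmetric tensor."""
    v = np.asarray(voigt, dtype=float)
    T = np.empty(v.shape[:-1] + (3, 3))
    T[..., 0, 0] = v[..., 0]
    T[..., 1, 1] = v[..., 1]
    T[..., 2, 2] = v[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = v[..., 3] * shear_factor
    T[..., 0, 2] = T[..., 2, 0] = v[..., 4] * shear_factor
    T[..., 1, 2] = T[..., 2, 1] = v[..., 5] * shear_factor
    return T


def principal_strains(strain) -> tuple:
    """(eps_max, eps_min): extreme eigenvalues of the strain tensor(s).

    Accepts a symmetric 3x3 tensor or a Voigt vector with engineering shear.
    """
    t = np.asarray(strain, dtype=float)
    if t.shape[-1] == 6:
        t = _to_tensor(t, 0.5)  # engineering -> tensor shear
    else:
        if np.abs(t - np.swapaxes(t, -1, -2)).max() > 1e-10:
            raise PostprocessError("strain tensor is not symmetric")
    w = np.linalg.eigvalsh(t)
    return w[..., -1], w[..., 0]


def dominant_strain(eps_max, eps_min):
    """Signed principal strain of largest magnitude (ties -> tensile)."""
    eps_max = np.asarray(eps_max, dtype=float)
    eps_min = np.asarray(eps_min, dtype=float)
    if (eps_max < eps_min).any():
        raise PostprocessError("eps_max < eps_min")
    return np.where(np.abs(eps_max) >= np.abs(eps_min), eps_max, eps_min)


def von_mises(stress) -> np.ndarray:
    """von Mises equivalent stress from Voigt (11,22,33,12,13,23), MPa."""
    s = np.asarray(stress, dtype=float)
    if s.shape[-1] != 6:
        t = s
        s = np.stack(
            [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2],
             t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]], axis=-1
        )
    d1 = s[..., 0] - s[..., 1]
    d2 = s[..., 1] - s[..., 2]
    d3 = s[..., 2] - s[..., 0]
    sh = s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2
    return np.sqrt(0.5 * (d1**2 + d2**2 + d3**2) + 3.0 * sh)


@dataclass
class DevicePeak:
    """Peak von Mises stress of one device after singularity exclusion."""

    values: np.ndarray  # retained per-point von Mises, MPa
    peak: float  # MPa
    yield_strength: float
    yield_ratio: float
    n_excluded: int

    @property
    def elastic(self) -> bool:
        return self.yield_ratio < 1.0


def peak_device_stress(values, yield_strength: float) -> DevicePeak:
    """Exclude the top 0.1% of values, average the next 10 highest."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    if v.size < 20:
        raise PostprocessError("need at least 20 stress values")
    n_excl = int(np.ceil(0.001 * v.size))
    retained = v[n_excl:]
    peak = float(retained[:10].mean())
    return DevicePeak(
        values=retained,
        peak=peak,
        yield_strength=float(yield_strength),
        yield_ratio=peak / float(yield_strength),
        n_excluded=n_excl,
    )


def _box_stats(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"n": 0, "min": np.nan, "q1": np.nan, "median": np.nan,
                "q3": np.nan, "max": np.nan}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"n": int(x.size), "min": float(x.min()), "q1": float(q1),
            "median": float(med), "q3": float(q3), "max": float(x.max())}


@dataclass
class HealingSummary:
    """Dominant-strain statistics over the healing region (percent units)."""

    dominant_pct: np.ndarray  # signed, % at every integration point
    tensile: dict  # box stats of tensile magnitudes, %
    compressive: dict  # box stats of compressive magnitudes, %
    fraction_under_15pct: float
    median_abs_pct: float


def summarize_healing(solution, healing_elems=None, volume_weighted=False) -> HealingSummary:
    """Box statistics of the dominant principal strain in the healing region.

    Points are split by the sign of the dominant strain (zero counts as
    tensile); magnitudes are reported in percent.  By default every
    integration point counts equally; `volume_weighted` weights the quartiles
    by integration-point volume.
    """
    mesh = solution.mesh
    if healing_elems is None:
        healing_elems = mesh.element_sets.get("healing_region")
    if healing_elems is None or len(healing_elems) == 0:
        raise PostprocessError("empty healing region")
    eps = solution.strain[healing_elems].reshape(-1, 6)
    emax, emin = principal_strains(eps)
    dom = dominant_strain(emax, emin) * 100.0

    tens = dom[dom >= 0.0]
    comp = -dom[dom < 0.0]
    if volume_weighted:
        w = solution.point_weights[healing_elems].reshape(-1)
        tens_stats = _weighted_box(dom[dom >= 0.0], w[dom >= 0.0])
        comp_stats = _weighted_box(-dom[dom < 0.0], w[dom < 0.0])
    else:
        tens_stats = _box_stats(tens)
        comp_stats = _box_stats(comp)
    return HealingSummary(
        dominant_pct=dom,
        tensile=tens_stats,
        compressive=comp_stats,
        fraction_under_15pct=float((np.abs(dom) < 15.0).mean()),
        median_abs_pct=float(np.median(np.abs(dom))),
    )


def _weighted_box(x: np.ndarray, w: np.ndarray) -> dict:
    if x.size == 0:
        return _box_stats(x)
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    q1, med, q3 = np.interp([0.25, 0.5, 0.75], cw, x)
    return {"n": int(x.size), "min": float(x.min()), "q1": float(q1),
            "median": float(med), "q3": float(q3), "max": float(x.max())}


def device_stress_summary(solution, yield_strength: float) -> DevicePeak:
    """Peak von Mises over all plate and screw integration points."""
    mesh = solution.mesh
    dev = np.nonzero(np.isin(mesh.region, ("plate", "screw")))[0]
    if dev.size == 0:
        raise PostprocessError("no device elements in the mesh")
    vm = von_mises(solution.stress[dev].reshape(-1, 6))
    return peak_device_stress(vm, yield_strength)
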