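"""Analytic test potentials for the synthetic systems.

A :class:`PotentialSpec` defines a separable external potential

    U(x, y, z) = U_z(z) + ½ k_r (x² + y²)

on a rectangular sampling box; outside the box U is +∞ (samplers reject,
quadrature integrates only inside).  Axial kinds:

* ``harmonic_well``   — ½ k (z − center)²
* ``double_well``     — h·[((z − center)/a)² − 1]², wells at center ± a
* ``gaussian_barrier``— h·exp(−(z − center)²/(2 w²))
* ``composite``       — sum of any of the above

These potentials stand in for the protein environment felt by a gas probe
along a channel axis; they have analytically known Boltzmann statistics so
every estimator in the pipeline can be validated against quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["PotentialSpec", "harmonic_well", "double_well", "gaussian_barrier", "composite"]


@dataclass(frozen=True)
class _Term:
    kind: str
    params: tuple[tuple[str, float], ...]

    def u_z(self, z: np.ndarray) -> np.ndarray:
        p = dict(self.params)
        z = np.asarray(z, dtype=float)
        if self.kind == "harmonic_well":
            return 0.5 * p["k"] * (z - p.get("center", 0.0)) ** 2
        if self.kind == "gaussian_barrier":
            w = p["width"]
            return p["height"] * np.exp(-((z - p.get("center", 0.0)) ** 2) / (2 * w**2))
        if self.kind == "double_well":
            a = p["half_separation"]
            return p["height"] * (((z - p.get("center", 0.0)) / a) ** 2 - 1) ** 2
        raise ValueError(f"unknown potential kind {self.kind!r}")


@dataclass(frozen=True)
class PotentialSpec:
    """Separable axial potential with harmonic radial confinement on a box.

    ``z_range`` bounds the axial domain; ``lateral_extent`` is the full x
    and y width of the box (centered on the axis); ``k_radial`` confines
    samples around the z-axis (0 = free within the box).  ``bulk_zranges``
    names the z slabs considered bulk solution for referencing; by default
    the outer 15% at each end of ``z_range``.
    """

    terms: tuple[_Term, ...]
    z_range: tuple[float, float] = (-20.0, 20.0)
    lateral_extent: float = 10.0
    k_radial: float = 0.5  # kcal/mol/Å²
    bulk_zranges: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if hi <= lo:
            raise ValueError("z_range must be increasing")
        if self.lateral_extent <= 0:
            raise ValueError("lateral_extent must be positive")
        if self.k_radial < 0:
            raise ValueError("k_radial must be >= 0")

    # -- evaluation ---------------------------------------------------------

    def u_z(self, z: np.ndarray) -> np.ndarray:
        """Axial part of the potential, kcal/mol; +∞ outside z_range."""
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for t in self.terms:
            u = u + t.u_z(z)
        lo, hi = self.z_range
        return np.where((z >= lo) & (z <= hi), u, np.inf)

    def u(self, xyz: np.ndarray) -> np.ndarray:
        """Full potential at (..., 3) points; +∞ outside the box."""
        xyz = np.asarray(xyz, dtype=float)
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        u = self.u_z(z) + 0.5 * self.k_radial * (x**2 + y**2)
        half = self.lateral_extent / 2
        inside = (np.abs(x) <= half) & (np.abs(y) <= half)
        return np.where(inside, u, np.inf)

    def default_bulk_zranges(self) -> tuple[tuple[float, float], ...]:
        if self.bulk_zranges is not None:
            return self.bulk_zranges
        lo, hi = self.z_range
        pad = 0.15 * (hi - lo)
        return ((lo, lo + pad), (hi - pad, hi))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "terms": [{"kind": t.kind, **dict(t.params)} for t in self.terms],
            "z_range": list(self.z_range),
            "lateral_extent": self.lateral_extent,
            "k_radial": self.k_radial,
            "bulk_zranges": None
            if self.bulk_zranges is None
            else [list(r) for r in self.bulk_zranges],
        }

    @staticmethod
    def from_dict(d: dict[str, Any]) -> "PotentialSpec":
        terms = tuple(
            _Term(
                kind=td["kind"],
                params=tuple((k, float(v)) for k, v in sorted(td.items()) if k != "kind"),
            )
            for td in d.get("terms", [])
        )
        return PotentialSpec(
            terms=terms,
            z_range=tuple(d.get("z_range", (-20.0, 20.0))),
            lateral_extent=float(d.get("lateral_extent", 10.0)),
            k_radial=float(d.get("k_radial", 0.5)),
            bulk_zranges=None
            if d.get("bulk_zranges") in (None, "null")
            else tuple(tuple(r) for r in d["bulk_zranges"]),
        )


def _mk(kind: str, /, **params: float) -> _Term:
    return _Term(kind=kind, params=tuple(sorted(params.items())))


def harmonic_well(k: float, center: float = 0.0, **box: Any) -> PotentialSpec:
    return PotentialSpec(terms=(_mk("harmonic_well", k=k, center=center),), **box)


def gaussian_barrier(height: float, center: float = 0.0, width: float = 1.5, **box: Any) -> PotentialSpec:
    return PotentialSpec(
        terms=(_mk("gaussian_barrier", height=height, center=center, width=width),), **box
    )


def double_well(height: float, half_separation: float, center: float = 0.0, **box: Any) -> PotentialSpec:
    return PotentialSpec(
        terms=(_mk("double_well", height=height, half_separation=half_separation, center=center),),
        **box,
    )


def composite(*specs: PotentialSpec, **box: Any) -> PotentialSpec:
    terms = tuple(t for s in specs for t in s.terms)
    return PotentialSpec(terms=terms, **box)
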