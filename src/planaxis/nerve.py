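"""Synthetic nerve-polarity transport fields and neural production maps.

The transport field u(x, y) encodes the net polarity of nerve axons: +u is
the kinesin (plus-end, soma -> terminal) direction, which runs anterior ->
posterior along the ventral nerve cords (VNC) of a one-headed (1H) worm.  A
two-headed (2H) worm carries a bipolar field, each half pointing from its
head toward a midbody symmetry line.

The neural production map G(x, y) weights morphogen synthesis in
nerve-bearing tissue and is obtained as the positive part of the discrete
divergence of u, normalized to a maximum of 1: where more axons originate
per unit tissue (high positive divergence) there are more nerve somata, and
hence more synthesis of neurally produced morphogens.

Fields are generated parametrically from a small set of anatomical knobs
(VNC offset, commissural weight, symmetry-line position) rather than traced
from stained specimens; externally derived fields can be loaded from CSV in
the same per-cell layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import Mesh

__all__ = [
    "NerveMapParams",
    "ProductionField",
    "VectorField",
    "generate_field",
    "production_from_divergence",
]


@dataclass
class NerveMapParams:
    """Anatomical parameters of the synthetic nerve map.

    body_plan : "1H" (monopolar) or "2H" (bipolar).
    vnc_offset : lateral half-offset of each VNC stripe from the midline (m).
    vnc_weight / commissure_weight : relative strengths of the AP-aligned VNC
        component and the laterally directed commissural component.
    symmetry_fraction : axial position of the 2H mirror line as a fraction of
        body length.
    ramp_weight : share of the axial magnitude profile that keeps growing
        linearly all the way to the tail; the remainder saturates over
        ``rise_fraction * L`` behind the head, concentrating axon origination
        (and hence production G) anteriorly.
    stripe_sigma : Gaussian half-width of a VNC stripe (m); defaults to half
        the VNC offset.
    """

    body_plan: str = "1H"
    vnc_offset: float = 3.5e-4
    vnc_weight: float = 1.0
    commissure_weight: float = 1.0
    commissure_angle_deg: float = 90.0
    symmetry_fraction: float = 0.5
    ramp_weight: float = 0.4
    rise_fraction: float = 0.08
    stripe_sigma: float | None = None

    def __post_init__(self):
        if self.body_plan not in ("1H", "2H"):
            raise ValueError("body_plan must be '1H' or '2H'")
        if self.vnc_weight < 0 or self.commissure_weight < 0:
            raise ValueError("component weights must be non-negative")
        if not 0 < self.symmetry_fraction < 1:
            raise ValueError("symmetry_fraction must lie in (0, 1)")
        if self.stripe_sigma is None:
            self.stripe_sigma = 0.5 * self.vnc_offset


class VectorField:
    """Per-cell transport direction, |u| <= 1.  In 1D only u_x is used."""

    def __init__(self, values: np.ndarray, mesh: Mesh):
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = np.column_stack([values, np.zeros_like(values)])
        if values.shape != (mesh.n_cells, 2):
            raise ValueError("field shape does not match mesh")
        norms = np.linalg.norm(values, axis=1)
        if np.any(norms > 1 + 1e-9):
            raise ValueError("|u| must not exceed 1")
        self.values = values
        self.mesh = mesh

    @property
    def ux(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def uy(self) -> np.ndarray:
        return self.values[:, 1]

    def face_normal_component(self) -> np.ndarray:
        """u . n̂ per face; face u is the arithmetic mean of the two adjacent
        cells, and a boundary face uses its single cell's value."""
        m = self.mesh
        a = m.face_cells[:, 0]
        b = m.face_cells[:, 1]
        ua = self.values[a]
        ub = np.where((b >= 0)[:, None], self.values[np.maximum(b, 0)], ua)
        uf = 0.5 * (ua + ub)
        return np.einsum("ij,ij->i", uf, m.face_normal)

    def restrict(self, cells: np.ndarray, mesh: Mesh) -> "VectorField":
        return VectorField(self.values[cells], mesh)

    def to_csv(self, path):
        pd.DataFrame(
            {
                "cell_id": np.arange(len(self.values)),
                "ux": self.values[:, 0],
                "uy": self.values[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mesh: Mesh) -> "VectorField":
        df = pd.read_csv(path).sort_values("cell_id")
        return cls(df[["ux", "uy"]].to_numpy(), mesh)


class ProductionField:
    """Per-cell production weight G in [0, 1]."""

    def __init__(self, values: np.ndarray, mesh: Mesh):
        values = np.asarray(values, dtype=float)
        if values.shape != (mesh.n_cells,):
            raise ValueError("field shape does not match mesh")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-9):
            raise ValueError("G must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)
        self.mesh = mesh

    def restrict(self, cells: np.ndarray, mesh: Mesh) -> "ProductionField":
        return ProductionField(self.values[cells], mesh)

    def to_csv(self, path):
        pd.DataFrame(
            {"cell_id": np.arange(len(self.values)), "G": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mesh: Mesh) -> "ProductionField":
        df = pd.read_csv(path).sort_values("cell_id")
        return cls(df["G"].to_numpy(), mesh)


def _axial_profile(s: np.ndarray, params: NerveMapParams) -> np.ndarray:
    """Monopolar axial magnitude on the normalized coordinate s in [0, 1].

    A blend of a linear ramp and a saturating rise: transport strength grows
    from zero at the anterior tip (no axons ahead of the head) toward the
    tail, while the *gradient* of the profile -- the axon origination density
    that becomes G -- is largest behind the head and decays posteriorly.
    """
    s = np.clip(s, 0.0, 1.0)
    a = params.ramp_weight
    rise = 1.0 - np.exp(-s / params.rise_fraction)
    return a * s + (1.0 - a) * rise


def _half_width_interp(mesh: Mesh):
    """Local body half-width w(x) interpolated from the outline."""
    if mesh.outline is None:
        wmax = max(np.abs(mesh.points[:, 1]).max(), 1e-12)
        return lambda x: np.full_like(np.asarray(x, dtype=float), wmax)
    verts = mesh.outline.vertices
    top = verts[verts[:, 1] >= 0]
    order = np.argsort(top[:, 0])
    xs, ws = top[order, 0], top[order, 1]
    return lambda x: np.interp(x, xs, ws)


def generate_field(mesh: Mesh, params: NerveMapParams) -> VectorField:
    """Synthesize the nerve-polarity transport field for a body plan.

    1H: an AP-aligned component concentrated in two VNC stripes at
    ``y = +/- vnc_offset`` (pointing +x) blended with a commissural component
    in the lateral margins pointing outward (+/- y), bilaterally symmetric
    about the midline.  1D grids reduce to the axial profile alone.

    2H: the 1H construction mirrored about the symmetry line, each half
    pointing away from its own head.
    """
    x = mesh.points[:, 0]
    y = mesh.points[:, 1]
    L = x.max() - x.min() if mesh.outline is None else mesh.outline.length
    if L <= 0:
        L = max(x.max(), 1e-12)
    s = (x - x.min()) / L if mesh.outline is None else x / L

    if params.body_plan == "1H":
        axial = _axial_profile(s, params)
        sign = np.ones_like(s)
    else:
        f = params.symmetry_fraction
        anterior = s <= f
        axial = np.where(
            anterior,
            _axial_profile(s / f, params),
            _axial_profile((1.0 - s) / (1.0 - f), params),
        )
        sign = np.where(anterior, 1.0, -1.0)

    if mesh.dim == 1:
        return VectorField(np.clip(sign * axial, -1.0, 1.0), mesh)

    w_of_x = _half_width_interp(mesh)
    w = np.maximum(w_of_x(x), 1e-12)
    if np.median(w) < 1.5 * params.vnc_offset:
        warnings.warn(
            "outline too thin to hold distinct VNC stripes; "
            "falling back to a pure AP-aligned field",
            stacklevel=2,
        )
        ux = sign * axial
        return VectorField(np.column_stack([ux, np.zeros_like(ux)]), mesh)

    stripe = np.exp(-(((np.abs(y) - params.vnc_offset) / params.stripe_sigma) ** 2))
    vnc = params.vnc_weight * stripe * axial
    marg = np.clip(
        (np.abs(y) - params.vnc_offset) / np.maximum(w - params.vnc_offset, 1e-12),
        0.0,
        1.0,
    )
    comm = params.commissure_weight * marg * np.sign(y)
    u = np.column_stack([sign * vnc, comm])
    norms = np.linalg.norm(u, axis=1)
    over = norms > 1.0
    u[over] /= norms[over, None]
    return VectorField(u, mesh)


def production_from_divergence(field: VectorField, mesh: Mesh) -> ProductionField:
    """Neural production map: normalized positive part of div u.

    The discrete divergence uses the same finite-volume face sum as the
    transport solver, so morphogen is produced exactly where the transport
    operator sees axons originate.  Negative divergence (axon convergence)
    carries no somata and is clamped to zero before normalization.
    """
    if field.mesh is not mesh and field.mesh.n_cells != mesh.n_cells:
        raise ValueError("field and mesh are inconsistent")
    div = mesh.divergence(field.face_normal_component())
    g = np.clip(div, 0.0, None)
    gmax = g.max()
    if gmax <= 0:
        warnings.warn(
            "transport field has no positive divergence; production map is zero",
            stacklevel=2,
        )
        return ProductionField(np.zeros(mesh.n_cells), mesh)
    return ProductionField(g / gmax, mesh)


def raw_divergence(field: VectorField, mesh: Mesh) -> np.ndarray:
    """Unclamped, unnormalized discrete divergence of the transport field."""
    return mesh.divergence(field.face_normal_component())
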