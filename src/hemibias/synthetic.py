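"""Latent-component simulator for bilateral ROI time courses.

Each simulated series mixes four unit-variance latent sources::

    x[s, R, h](t) = alpha * g_R(t) + beta * u[s, R](t) + gamma * v[s, h](t)
                    + sigma * e(t)

* ``g_R`` -- stimulus-driven drive, shared by every subject and both
  hemispheres; distinct regions share it with equicorrelation ``rho_g``.
* ``u[s, R]`` -- subject-specific homotopic drive, shared by the two
  hemispheres of one subject's region and nothing else.
* ``v[s, h]`` -- subject-specific hemispheric drive, shared by all regions
  within one hemisphere of one subject.
* ``e`` -- independent noise.

This structure gives closed-form expected Pearson correlations for every
pairing class used in the homotopic-connectivity analysis (within- and
between-subject, corresponding / non-corresponding interhemispheric, and
intrahemispheric), so sampled tables can be checked against ground truth.

Latents are white Gaussian by default.  An optional AR(1) coefficient adds
temporal autocorrelation (BOLD-like smoothness) with the marginal variance
renormalised to one, so the closed forms above still hold at lag zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import lfilter


class PairClass(str, Enum):
    """Region-pair classes of the interhemispheric-bias analysis."""

    INTER_CORRESPONDING = "inter_corresponding"
    INTER_NONCORRESPONDING = "inter_noncorresponding"
    INTRA = "intra"
    BETWEEN_INTER_CORRESPONDING = "between_inter_corresponding"
    BETWEEN_INTER_NONCORRESPONDING = "between_inter_noncorresponding"
    BETWEEN_INTRA = "between_intra"


HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class LatentSpec:
    """Generative parameters for one network regime.

    Parameters
    ----------
    regions
        Ordered region names (each exists in both hemispheres).
    alpha
        Weight of the stimulus component shared across subjects (>= 0).
    beta
        Weight of the subject-specific homotopic component (>= 0).
    gamma
        Weight of the subject-specific hemispheric component (>= 0).
    sigma
        Independent noise standard deviation (> 0 in practice; the total
        variance ``alpha**2 + beta**2 + gamma**2 + sigma**2`` must be > 0).
    rho_g
        Equicorrelation of the stimulus component between distinct regions,
        in [0, 1].
    ar_phi
        Optional AR(1) coefficient applied to every latent series, in
        [0, 1).  Zero (default) keeps latents white.
    """

    regions: tuple[str, ...]
    alpha: float
    beta: float
    gamma: float
    sigma: float
    rho_g: float = 0.0
    ar_phi: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) == 0:
            raise ValueError("at least one region is required")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")
        for name in ("alpha", "beta", "gamma", "sigma"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val!r}")
        if self.total_variance <= 0:
            raise ValueError("total variance alpha^2+beta^2+gamma^2+sigma^2 must be > 0")
        if not 0.0 <= self.rho_g <= 1.0:
            raise ValueError(f"rho_g must lie in [0, 1], got {self.rho_g!r}")
        n = len(self.regions)
        if n > 1 and self.rho_g < -1.0 / (n - 1):
            raise ValueError("rho_g violates the equicorrelation PSD bound")
        if not 0.0 <= self.ar_phi < 1.0:
            raise ValueError(f"ar_phi must lie in [0, 1), got {self.ar_phi!r}")

    @property
    def total_variance(self) -> float:
        return self.alpha**2 + self.beta**2 + self.gamma**2 + self.sigma**2


#: Named parameter regimes.  ``face_scene`` puts more weight on the homotopic
#: than the hemispheric component (interhemispheric bias, as seen in
#: category-selective networks); ``early_visual`` reverses that ordering;
#: ``null`` matches the corresponding-interhemispheric and intrahemispheric
#: expected correlations exactly (beta == gamma, rho_g == 1) so the bias
#: statistic has zero expectation.
PRESETS: dict[str, dict[str, float]] = {
    "face_scene": dict(alpha=0.4, beta=0.7, gamma=0.3, sigma=1.0, rho_g=0.5),
    "early_visual": dict(alpha=0.6, beta=0.3, gamma=0.7, sigma=1.0, rho_g=0.6),
    "null": dict(alpha=0.5, beta=0.5, gamma=0.5, sigma=1.0, rho_g=1.0),
}

#: Bilateral region sets of the three functional networks.
NETWORK_REGIONS: dict[str, tuple[str, ...]] = {
    "face": ("OFA", "FFA", "pSTS", "AMG"),
    "scene": ("OPA", "PPA", "RSC"),
    "early_visual": ("V1d", "V2d", "V3d", "V1v", "V2v", "V3v"),
}

#: Which preset regime each named network follows.
NETWORK_PRESET: dict[str, str] = {
    "face": "face_scene",
    "scene": "face_scene",
    "early_visual": "early_visual",
}


def preset_spec(name: str, regions: tuple[str, ...] | None = None, **overrides) -> LatentSpec:
    """Build a :class:`LatentSpec` from a named preset regime.

    ``name`` may be a preset (``face_scene``, ``early_visual``, ``null``) or
    a network name (``face``, ``scene``, ``early_visual``), in which case the
    network's region list and its regime are used.
    """
    if name in NETWORK_REGIONS:
        params = dict(PRESETS[NETWORK_PRESET[name]])
        if regions is None:
            regions = NETWORK_REGIONS[name]
    elif name in PRESETS:
        params = dict(PRESETS[name])
        if regions is None:
            regions = NETWORK_REGIONS["face"]
    else:
        raise KeyError(f"unknown preset or network {name!r}; "
                       f"choose from {sorted(PRESETS) + sorted(NETWORK_REGIONS)}")
    params.update(overrides)
    return LatentSpec(regions=tuple(regions), **params)


@dataclass
class ROITimecourseDataset:
    """Per subject x region x hemisphere time courses with run boundaries.

    ``data`` has shape ``(n_subjects, n_regions, 2, T)`` with hemisphere
    axis ordered L, R and ``T = sum(run_lengths)``.  Values are in
    percent-signal-change-like units (zero mean per latent construction).
    """

    data: np.ndarray
    regions: tuple[str, ...]
    run_lengths: tuple[int, ...]
    network: str = "network"
    spec: LatentSpec | None = None
    seed: int | None = None
    hemispheres: tuple[str, str] = HEMISPHERES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.regions = tuple(self.regions)
        self.run_lengths = tuple(int(r) for r in self.run_lengths)
        if self.data.ndim != 4 or self.data.shape[1] != len(self.regions) or self.data.shape[2] != 2:
            raise ValueError("data must have shape (n_subjects, n_regions, 2, T)")
        if self.data.shape[3] != sum(self.run_lengths):
            raise ValueError("time axis length must equal the sum of run lengths")
        if not np.isfinite(self.data).all():
            raise ValueError("dataset contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def series(self, subject: int, region: str, hemisphere: str) -> np.ndarray:
        """Return one subject/region/hemisphere series (a view)."""
        r = self.regions.index(region)
        h = self.hemispheres.index(hemisphere)
        return self.data[subject, r, h]

    def node_matrix(self, subject: int) -> np.ndarray:
        """All 2*n_regions series of one subject, shape (n_nodes, T).

        Node order matches :func:`hemibias.connectivity.layout_nodes`:
        region-major, hemisphere L before R.
        """
        return self.data[subject].reshape(-1, self.n_timepoints)


def _ar1(white: np.ndarray, phi: float) -> np.ndarray:
    """Filter white N(0,1) innovations into a unit-variance AR(1) series.

    Stationary initialisation: the first sample keeps variance 1 and every
    subsequent innovation is scaled by sqrt(1 - phi^2).
    """
    if phi == 0.0:
        return white
    driven = white * np.sqrt(1.0 - phi * phi)
    driven[..., 0] = white[..., 0]
    return lfilter([1.0], [1.0, -phi], driven, axis=-1)


def generate_dataset(
    spec: LatentSpec,
    n_subjects: int,
    run_lengths: list[int] | tuple[int, ...],
    seed: int,
    network: str = "network",
) -> ROITimecourseDataset:
    """Simulate a multi-subject bilateral ROI time-course dataset.

    The same ``seed`` always yields a bit-identical dataset.  Latents are
    drawn over the full concatenated length; run boundaries are metadata for
    downstream per-run handling.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    run_lengths = tuple(int(r) for r in run_lengths)
    if len(run_lengths) == 0:
        raise ValueError("at least one run is required")
    if any(r < 2 for r in run_lengths):
        raise ValueError("each run length must be >= 2")

    n_reg = len(spec.regions)
    T = sum(run_lengths)
    rng = np.random.default_rng(seed)

    # Stimulus component: equicorrelated across regions via a shared factor.
    common = rng.standard_normal(T)
    distinct = rng.standard_normal((n_reg, T))
    g = np.sqrt(spec.rho_g) * common + np.sqrt(1.0 - spec.rho_g) * distinct

    u = rng.standard_normal((n_subjects, n_reg, T))       # homotopic
    v = rng.standard_normal((n_subjects, 2, T))           # hemispheric
    e = rng.standard_normal((n_subjects, n_reg, 2, T))    # noise

    if spec.ar_phi:
        g = _ar1(g, spec.ar_phi)
        u = _ar1(u, spec.ar_phi)
        v = _ar1(v, spec.ar_phi)
        e = _ar1(e, spec.ar_phi)

    data = (
        spec.alpha * g[None, :, None, :]
        + spec.beta * u[:, :, None, :]
        + spec.gamma * v[:, None, :, :]
        + spec.sigma * e
    )
    return ROITimecourseDataset(
        data=data,
        regions=spec.regions,
        run_lengths=run_lengths,
        network=network,
        spec=spec,
        seed=seed,
    )


def analytic_pair_correlation(spec: LatentSpec, pair_class: PairClass | str) -> float:
    """Closed-form expected Pearson correlation for a pairing class.

    With total variance ``V = alpha^2 + beta^2 + gamma^2 + sigma^2``:

    ===============================  =============================
    inter_corresponding              (alpha^2 + beta^2) / V
    intra                            (alpha^2 rho_g + gamma^2) / V
    inter_noncorresponding           alpha^2 rho_g / V
    between_inter_corresponding      alpha^2 / V
    between_intra                    alpha^2 rho_g / V
    between_inter_noncorresponding   alpha^2 rho_g / V
    ===============================  =============================
    """
    pair_class = PairClass(pair_class)
    V = spec.total_variance
    if V <= 0:
        raise ValueError("total variance must be > 0")
    a2, b2, c2 = spec.alpha**2, spec.beta**2, spec.gamma**2
    if pair_class is PairClass.INTER_CORRESPONDING:
        num = a2 + b2
    elif pair_class is PairClass.INTRA:
        num = a2 * spec.rho_g + c2
    elif pair_class is PairClass.INTER_NONCORRESPONDING:
        num = a2 * spec.rho_g
    elif pair_class is PairClass.BETWEEN_INTER_CORRESPONDING:
        num = a2
    else:  # between_intra, between_inter_noncorresponding
        num = a2 * spec.rho_g
    return num / V


# ---------------------------------------------------------------------------
# Synthetic localiser-style statistical maps and surfaces


def generate_statmap(
    shape: tuple[int, int, int],
    voxel_size: float | tuple[float, float, float],
    peaks: list[tuple[tuple[float, float, float], float, float]],
    seed: int | None = None,
    noise_sd: float = 0.0,
):
    """Deterministic 3D scalar field made of isotropic Gaussian bumps.

    Parameters
    ----------
    shape
        Grid dimensions (nx, ny, nz), all positive.
    voxel_size
        Voxel edge length(s) in mm.
    peaks
        ``(centre_voxel, amplitude, width_voxels)`` triples; each centre
        must lie inside the grid.  Widths are the Gaussian sigma in voxels.
    seed, noise_sd
        Optional additive white Gaussian noise.

    Returns
    -------
    StatMap
        With ``values = sum_k amp_k * exp(-|x - c_k|^2 / (2 w_k^2))``
        (+ noise).  When bumps are well separated the argmax of each bump
        is its stated centre.
    """
    from .roi import StatMap  # local import to avoid a cycle

    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError("shape must be three positive integers")
    values = np.zeros(shape, dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    for centre, amplitude, width in peaks:
        centre = tuple(float(c) for c in centre)
        if len(centre) != 3 or any(c < 0 or c > s - 1 for c, s in zip(centre, shape)):
            raise ValueError(f"peak centre {centre} lies outside the grid {shape}")
        if width <= 0:
            raise ValueError("peak width must be > 0")
        d2 = sum((gr - c) ** 2 for gr, c in zip(grids, centre))
        values += amplitude * np.exp(-d2 / (2.0 * width * width))
    if noise_sd:
        rng = np.random.default_rng(seed)
        values += noise_sd * rng.standard_normal(shape)
    return StatMap(values=values, voxel_size=voxel_size)


def generate_surface(level: int, radius: float, stat_direction):
    """Icosphere mesh with per-vertex scalars peaked along a direction.

    The scalar at each vertex is the dot product of the vertex unit normal
    (radial direction on a sphere) with ``stat_direction``, so the unique
    maximum sits at the vertex nearest that direction.  Subdivision level 0
    is the icosahedron (12 vertices, 20 faces); the mesh is a closed
    2-manifold with Euler characteristic 2 at every level.
    """
    import trimesh

    from .roi import SurfaceMesh

    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    direction = np.asarray(stat_direction, dtype=float)
    if direction.shape != (3,) or not np.isfinite(direction).all():
        raise ValueError("stat_direction must be a finite 3-vector")
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("stat_direction must be non-zero")
    direction = direction / norm

    mesh = trimesh.creation.icosphere(subdivisions=level, radius=radius)
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    unit_normals = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
    scalars = unit_normals @ direction
    return SurfaceMesh(vertices=vertices, faces=faces, scalars=scalars)
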