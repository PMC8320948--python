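"""Synthetic serial block-face SEM phantoms with exact ground truth.

The generator emulates the appearance of a cropped HeLa-cell sub-volume as
the segmentation pipeline sees it, at a reduced, desk-scale grid:

* bright, homogeneous background (embedding resin);
* a darker cytoplasm partitioned by dark membranes into closed compartments
  (a Voronoi foam standing in for ER, mitochondria and vesicles), which —
  exactly as in real micrographs — shatters the cytoplasm into many small
  edge-bounded fragments instead of leaving large open regions;
* a thin, dark nuclear envelope drawn as a shell straddling the true nucleus
  boundary, around a mid-grey, mildly textured nucleoplasm;
* the nucleus itself is a radially perturbed sphere (in physical
  coordinates) whose smooth angular deformation field is scaled by
  ``deform_amplitude``; an optional polar groove of given depth and width
  makes near-pole cross-sections split into disjoint islands;
* dark fragments of neighbouring cells touching the image borders;
* additive Gaussian noise and an optional rigid inter-slice shift artefact.

All randomness comes from one seeded generator, so identical parameters give
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .align import translate_slice
from .stackio import DEFAULT_VOXEL_SIZE, ImageStack
from .volume import extract_envelope


@dataclass
class PhantomParams:
    """Phantom geometry, contrast and noise settings.

    Intensities are 8-bit grey levels and must respect the contrast ordering
    the segmenter relies on: background > nucleoplasm > envelope.  The
    nucleus radius is in in-plane voxels; with the default anisotropic voxel
    size the nucleus occupies ``radius / 5`` slices either side of centre.
    """

    shape: tuple[int, int, int] = (256, 256, 60)
    nucleus_radius: float = 100.0
    deform_amplitude: float = 0.05
    notch_depth: float = 0.0
    notch_width: float = 0.0
    background_intensity: int = 208
    cytoplasm_intensity: int = 112
    nucleoplasm_intensity: int = 144
    envelope_intensity: int = 48
    envelope_thickness: float = 5.0
    noise_sigma: float = 6.0
    clutter_count: int = 6
    cytoplasm_margin: float = 25.0
    shift_artifact: tuple[int, int, int] | None = None
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.background_intensity
            > self.nucleoplasm_intensity
            > self.envelope_intensity
        ):
            raise ValueError(
                "intensity ordering violated: need background > nucleoplasm > envelope"
            )
        if self.envelope_thickness < 1:
            raise ValueError("envelope_thickness must be >= 1 voxel")


class _AngularField:
    """Smooth band-limited random field on the sphere.

    A sum of a few low-order separable harmonics in latitude/longitude;
    longitude-dependent terms are damped by cos(lat)^m so the field stays
    smooth at the poles.  Normalised to unit maximum magnitude.
    """

    def __init__(self, rng: np.random.Generator, n_terms: int = 6):
        self.terms = []
        for _ in range(n_terms):
            l = int(rng.integers(1, 4))
            m = int(rng.integers(0, 4))
            w = float(rng.normal())
            alpha = float(rng.uniform(0.0, 2.0 * np.pi))
            beta = float(rng.uniform(0.0, 2.0 * np.pi))
            self.terms.append((l, m, w, alpha, beta))
        lat = np.linspace(-np.pi / 2, np.pi / 2, 91)[:, None]
        lon = np.linspace(0.0, 2.0 * np.pi, 181)[None, :]
        self.scale = max(float(np.abs(self._raw(lat, lon)).max()), 1e-9)

    def _raw(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast(lat, lon).shape)
        for l, m, w, alpha, beta in self.terms:
            out += (
                w
                * np.cos(l * lat + alpha)
                * np.cos(lat) ** m
                * np.cos(m * lon + beta)
            )
        return out

    def __call__(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        return self._raw(lat, lon) / self.scale


def _physical_coords(params: PhantomParams):
    n_h, n_w, n_d = params.shape
    vr, vc, vs = params.voxel_size
    c = ((n_h - 1) / 2.0, (n_w - 1) / 2.0, (n_d - 1) / 2.0)
    pr = (np.arange(n_h) - c[0])[:, None, None] * vr
    pc = (np.arange(n_w) - c[1])[None, :, None] * vc
    ps = (np.arange(n_d) - c[2])[None, None, :] * vs
    return pr, pc, ps


def _nucleus_mask(params: PhantomParams, field: _AngularField) -> np.ndarray:
    """Deformed-ball ground truth, with optional polar groove."""
    pr, pc, ps = _physical_coords(params)
    vr = params.voxel_size[0]
    rho = np.sqrt(pr**2 + pc**2 + ps**2)
    rho_safe = np.maximum(rho, 1e-9)
    lat = np.arcsin(np.clip(ps / rho_safe, -1.0, 1.0))
    lon = np.arctan2(pc, pr)
    r0 = params.nucleus_radius * vr
    radius = r0 * (1.0 + params.deform_amplitude * field(lat, lon))
    mask = rho <= radius
    if params.notch_depth > 0 and params.notch_width > 0:
        half_w = params.notch_width * vr / 2.0
        z_cut = r0 - params.notch_depth * vr
        groove = (np.abs(pc) <= half_w) & (ps >= z_cut)
        mask &= ~groove
    return mask


def _render(params: PhantomParams, rng: np.random.Generator, gt: np.ndarray) -> np.ndarray:
    """Paint the greyscale volume around the ground-truth nucleus."""
    n_h, n_w, n_d = params.shape
    vr = params.voxel_size[0]
    pr, pc, ps = _physical_coords(params)
    rho = np.sqrt(pr**2 + pc**2 + ps**2)

    img = np.full(params.shape, float(params.background_intensity))

    # cell body: sphere comfortably containing the deformed nucleus
    cell_radius = (1.0 + abs(params.deform_amplitude)) * params.nucleus_radius * vr
    cell_radius += params.cytoplasm_margin * vr
    cell = rho <= cell_radius
    cyt = cell & ~gt
    img[cyt] = params.cytoplasm_intensity

    # membranous foam: dark membranes partition the cytoplasm into closed
    # compartments (Voronoi cells of random seed points), mimicking the
    # dense organelle packing of EM cytoplasm at ~160 nm spacing
    if cyt.any():
        spacing = 160.0  # nm between compartment centres
        membrane_half = 25.0  # nm: |d2 - d1| below this renders as membrane
        extent = [p.max() - p.min() for p in (pr, pc, ps)]
        n_seeds = max(8, int(np.prod([e / spacing for e in extent])))
        seeds = np.column_stack(
            [rng.uniform(p.min(), p.max(), n_seeds) for p in (pr, pc, ps)]
        )
        tree = cKDTree(seeds)
        coords = np.column_stack(
            [np.broadcast_to(p, params.shape)[cyt] for p in (pr, pc, ps)]
        )
        dist, idx = tree.query(coords, k=2)
        membrane = (dist[:, 1] - dist[:, 0]) < 2.0 * membrane_half
        compartment_shade = rng.uniform(-10.0, 10.0, n_seeds)
        membrane_intensity = max(
            params.envelope_intensity + 8, params.cytoplasm_intensity - 56
        )
        shades = params.cytoplasm_intensity + compartment_shade[idx[:, 0]]
        img[cyt] = np.where(membrane, membrane_intensity, shades)

    # nucleoplasm: mid grey with gentle chromatin-like texture
    chroma = ndi.gaussian_filter(rng.standard_normal(params.shape), (4.0, 4.0, 2.0))
    chroma *= 5.0 / max(chroma.std(), 1e-9)
    img[gt] = np.clip(params.nucleoplasm_intensity + chroma[gt], 0, 255)

    # envelope: dark shell of the stated thickness straddling the gt boundary
    half_t = params.envelope_thickness / 2.0
    for k in range(n_d):
        g = gt[:, :, k]
        if not g.any():
            continue
        d_in = ndi.distance_transform_edt(g)
        d_out = ndi.distance_transform_edt(~g)
        shell = (g & (d_in <= half_t + 0.5)) | (~g & (d_out <= half_t))
        img[:, :, k][shell] = params.envelope_intensity

    # border-touching fragments of neighbouring cells
    for _ in range(params.clutter_count):
        side = int(rng.integers(4))
        along = float(rng.uniform(0.15, 0.85))
        if side == 0:
            r0_, c0_ = 0.0, along * (n_w - 1)
        elif side == 1:
            r0_, c0_ = float(n_h - 1), along * (n_w - 1)
        elif side == 2:
            r0_, c0_ = along * (n_h - 1), 0.0
        else:
            r0_, c0_ = along * (n_h - 1), float(n_w - 1)
        s0_ = float(rng.uniform(0.2, 0.8) * (n_d - 1))
        rr = float(rng.uniform(18.0, 40.0))
        rz = float(rng.uniform(2.0, 6.0))
        rlo, rhi = int(max(0, r0_ - rr - 1)), int(min(n_h, r0_ + rr + 2))
        clo, chi = int(max(0, c0_ - rr - 1)), int(min(n_w, c0_ + rr + 2))
        slo, shi = int(max(0, s0_ - rz - 1)), int(min(n_d, s0_ + rz + 2))
        rg = np.arange(rlo, rhi)[:, None, None]
        cg = np.arange(clo, chi)[None, :, None]
        sg = np.arange(slo, shi)[None, None, :]
        q = ((rg - r0_) / rr) ** 2 + ((cg - c0_) / rr) ** 2 + ((sg - s0_) / rz) ** 2
        box = img[rlo:rhi, clo:chi, slo:shi]
        free = ~cell[rlo:rhi, clo:chi, slo:shi]
        box[(q <= 1.0) & free] = params.cytoplasm_intensity - 16
        box[(q <= 1.0) & (q > 0.72) & free] = params.envelope_intensity + 8

    img += rng.normal(0.0, params.noise_sigma, params.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_phantom(
    params: PhantomParams | None = None,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Generate one phantom: (image stack, gt nucleus mask, gt envelope).

    Deterministic for fixed parameters (including the seed).  The ground
    truth envelope is exactly the per-slice inner boundary of the nucleus
    mask.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(params.seed)
    angular = _AngularField(rng)  # drawn first: same seed, same shape family
    gt = _nucleus_mask(params, angular)
    img = _render(params, rng, gt)

    if params.shift_artifact is not None:
        idx, dr, dc = params.shift_artifact
        for k in range(idx, params.shape[2]):
            img[:, :, k] = translate_slice(
                img[:, :, k], dr, dc, fill=params.background_intensity
            )
            gt[:, :, k] = translate_slice(gt[:, :, k], dr, dc, fill=False)

    envelope = extract_envelope(gt)
    return ImageStack(img, voxel_size=params.voxel_size), gt, envelope


def generate_cohort(
    n_cells: int = 7,
    amplitude_ladder: list[float] | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[tuple[ImageStack, np.ndarray, np.ndarray]]:
    """Generate a cohort of phantoms over an increasing deformation ladder.

    All cells share one deformation field shape (the common seed) so that the
    ladder isolates the amplitude effect: spheroid similarity falls and
    surface roughness rises monotonically along the cohort.  Default cells
    are smaller than the single-cell phantom to keep cohort studies quick.
    """
    if n_cells < 2:
        raise ValueError("a cohort needs at least 2 cells")
    if amplitude_ladder is None:
        amplitude_ladder = list(np.linspace(0.04, 0.28, n_cells))
    if len(amplitude_ladder) != n_cells:
        raise ValueError("amplitude ladder length must equal n_cells")
    if any(b <= a for a, b in zip(amplitude_ladder, amplitude_ladder[1:])):
        raise ValueError("amplitude ladder must be strictly increasing")
    if base_params is None:
        base_params = PhantomParams(shape=(128, 128, 48), nucleus_radius=45.0)
    out = []
    for amp in amplitude_ladder:
        params = replace(base_params, deform_amplitude=float(amp), seed=seed)
        out.append(generate_phantom(params))
    return out
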