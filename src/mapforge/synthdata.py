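"""Synthetic backbones, density maps and oracle probability volumes.

Every pipeline stage is testable without downloading deposited maps or
running a trained voxel classifier: this module generates (a) a protein
backbone whose consecutive Calpha atoms sit ~3.8 Angstrom apart, built
from ideal alpha-helix geometry, near-extended strand zigzags and a
self-avoiding random walk for coil; (b) a density volume of atom-centered
Gaussian blobs plus noise; (c) oracle per-voxel class-probability volumes
whose sharpness is set by a single ``fidelity`` knob — at fidelity 1 the
argmax reproduces the label masks exactly, and lower fidelity smears
probability mass over the wrong classes.

These volumes emulate classifier *outputs*, not experimental maps; real
maps carry non-Gaussian noise, missing density and artifacts that no blob
model reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridio import DensityGrid
from .labeler import (
    CODE_TO_ONE,
    SS_COIL,
    SS_HELIX,
    SS_STRAND,
    BackboneResidue,
    LabelMask,
    coord_to_index,
)

#: ideal alpha-helix Calpha parameterization: radius (A), rise per residue
#: (A), twist per residue (degrees) -> 3.83 A between consecutive Calphas
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0

CA_STEP = 3.8  # target consecutive-Calpha spacing (Angstrom)
MIN_NONCONSEC_DIST = 3.0  # self-avoidance for |i-j| >= 2
MAP_MARGIN = 5.0  # Angstrom of empty margin around the structure


class GenerationError(RuntimeError):
    """Self-avoiding placement failed after bounded retries."""


@dataclass
class SynthSpec:
    """Study conditions for one synthetic example.

    ``motif_mix`` gives (helix, strand, coil) fractions summing to 1;
    ``fidelity`` in [0, 1] is the oracle-prediction sharpness.
    """

    n_residues: int = 30
    motif_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    voxel_size: float = 1.0
    blob_sigma: float = 1.0
    noise_sigma: float = 0.05
    fidelity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.motif_mix) - 1.0) > 1e-9:
            raise ValueError("motif fractions must sum to 1")
        if not 0.0 <= self.fidelity <= 1.0:
            raise ValueError(f"fidelity {self.fidelity} outside [0, 1]")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")


def _helix_points(n: int) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(HELIX_TWIST_DEG)
    return np.column_stack([
        HELIX_RADIUS * np.cos(t),
        HELIX_RADIUS * np.sin(t),
        HELIX_RISE * np.arange(n),
    ])


def _strand_points(n: int) -> np.ndarray:
    # zigzag with alternating 0.5 A perpendicular offset; step chosen so the
    # chord is exactly CA_STEP
    offset = 0.5
    step = np.sqrt(CA_STEP**2 - (2 * offset) ** 2)
    pts = np.zeros((n, 3))
    pts[:, 2] = step * np.arange(n)
    pts[:, 0] = offset * (-1) ** np.arange(n)
    return pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _segment_lengths(n_residues: int, motif_mix, rng) -> list[tuple[str, int]]:
    kinds = ("helix", "strand", "coil")
    counts = [int(round(f * n_residues)) for f in motif_mix]
    counts[2] = n_residues - counts[0] - counts[1]
    if counts[2] < 0:
        counts[1] += counts[2]
        counts[2] = 0
    segments = [(k, c) for k, c in zip(kinds, counts) if c > 0]
    rng.shuffle(segments)
    return segments


def _clash_free(points: list[np.ndarray], candidate: np.ndarray,
                skip_last: int = 1) -> bool:
    if len(points) <= skip_last:
        return True
    prior = np.asarray(points[: len(points) - skip_last])
    return bool(np.min(np.linalg.norm(prior - candidate, axis=1))
                >= MIN_NONCONSEC_DIST)


def make_backbone(spec: SynthSpec) -> tuple[list[BackboneResidue], str]:
    """Generate a single-chain backbone and its one-letter sequence.

    Consecutive Calpha atoms are CA_STEP apart (helix chord 3.83 A); amide N
    and carbonyl C sit on the Calpha-Calpha segments. Amino types are drawn
    uniformly over the 20 standard residues (the default background table of
    the tracing module) with the spec's seed.

    Raises
    ------
    GenerationError
        If self-avoiding placement keeps clashing after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    segments = _segment_lengths(spec.n_residues, spec.motif_mix, rng)

    for _attempt in range(200):
        points: list[np.ndarray] = []
        ss_codes: list[int] = []
        ok = True
        for kind, length in segments:
            if kind == "helix":
                local, code = _helix_points(length), SS_HELIX
            elif kind == "strand":
                local, code = _strand_points(length), SS_STRAND
            else:
                local, code = None, SS_COIL

            if kind == "coil":
                # self-avoiding walk with limited bend per step
                placed = 0
                direction = _random_rotation(rng)[:, 2]
                for _ in range(length):
                    start = points[-1] if points else np.zeros(3)
                    for _try in range(50):
                        bend = rng.normal(scale=0.5, size=3)
                        d = direction + bend
                        d /= np.linalg.norm(d)
                        cand = start + CA_STEP * d
                        if _clash_free(points, cand):
                            break
                    else:
                        ok = False
                        break
                    points.append(cand)
                    ss_codes.append(code)
                    direction = d
                    placed += 1
                if not ok:
                    break
                continue

            for _try in range(50):
                rot = _random_rotation(rng)
                seg = local @ rot.T
                if points:
                    d = _random_rotation(rng)[:, 2]
                    anchor = points[-1] + CA_STEP * d
                else:
                    anchor = np.zeros(3)
                seg = seg - seg[0] + anchor
                if all(_clash_free(points + list(seg[:m]), seg[m])
                       for m in range(len(seg))):
                    break
            else:
                ok = False
                break
            points.extend(list(seg))
            ss_codes.extend([code] * length)
        if ok and len(points) == spec.n_residues:
            break
    else:
        raise GenerationError("could not place a self-avoiding backbone")

    ca = np.asarray(points)
    codes = rng.integers(1, 21, size=spec.n_residues)
    residues: list[BackboneResidue] = []
    for n in range(spec.n_residues):
        if n + 1 < spec.n_residues:
            seg = ca[n + 1] - ca[n]
        else:
            seg = ca[n] - ca[n - 1]
        c_xyz = ca[n] + seg / 3.0
        if n > 0:
            n_xyz = ca[n - 1] + 2.0 * (ca[n] - ca[n - 1]) / 3.0
        else:
            n_xyz = ca[n] - seg / 3.0
        residues.append(BackboneResidue(
            chain_id="A",
            residue_number=n + 1,
            amino_code=int(codes[n]),
            ca_xyz=tuple(ca[n]),
            n_xyz=tuple(n_xyz),
            c_xyz=tuple(c_xyz),
            ss_code=ss_codes[n],
        ))
    sequence = "".join(CODE_TO_ONE[int(c)] for c in codes)
    return residues, sequence


def simulate_map(structure: list[BackboneResidue], spec: SynthSpec,
                 ) -> DensityGrid:
    """Density volume: isotropic Gaussian blobs at every backbone atom plus
    zero-mean Gaussian noise, on a grid with a 5 A margin around the atoms."""
    if not structure:
        raise ValueError("structure is empty")
    rng = np.random.default_rng(spec.seed + 1)
    atoms = []
    for r in structure:
        for xyz in (r.ca_xyz, r.n_xyz, r.c_xyz):
            if xyz is not None:
                atoms.append(xyz)
    atoms = np.asarray(atoms)
    v = spec.voxel_size
    lo = np.floor(atoms.min(axis=0) - MAP_MARGIN)
    hi = atoms.max(axis=0) + MAP_MARGIN
    # grid arranged (z, y, x)
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / v)) + 1 for a in (2, 1, 0))
    data = np.zeros(shape, dtype=np.float64)

    reach = int(np.ceil(4 * spec.blob_sigma / v))
    zc = lo[2] + v * np.arange(shape[0])
    yc = lo[1] + v * np.arange(shape[1])
    xc = lo[0] + v * np.arange(shape[2])
    for x, y, z in atoms:
        iz = int(round((z - lo[2]) / v))
        iy = int(round((y - lo[1]) / v))
        ix = int(round((x - lo[0]) / v))
        sz = slice(max(iz - reach, 0), min(iz + reach + 1, shape[0]))
        sy = slice(max(iy - reach, 0), min(iy + reach + 1, shape[1]))
        sx = slice(max(ix - reach, 0), min(ix + reach + 1, shape[2]))
        dz = (zc[sz] - z)[:, None, None]
        dy = (yc[sy] - y)[None, :, None]
        dx = (xc[sx] - x)[None, None, :]
        data[sz, sy, sx] += np.exp(
            -(dx**2 + dy**2 + dz**2) / (2 * spec.blob_sigma**2))
    if spec.noise_sigma > 0:
        data += rng.normal(scale=spec.noise_sigma, size=shape)
    return DensityGrid(
        data=data,
        voxel_size=(v, v, v),
        origin=tuple(lo),
        labels=["synthetic blob map"],
    )


def _class_probs(mask_data: np.ndarray, n_classes: int, fidelity: float,
                 rng: np.random.Generator) -> np.ndarray:
    """(n_classes, nz, ny, nx) probability volume: the true class of every
    voxel gets ``fidelity``; the remainder is split over the other classes
    with random (seeded) proportions."""
    shape = mask_data.shape
    w = rng.random((n_classes,) + shape)
    onehot = np.zeros_like(w)
    idx = np.indices(shape)
    onehot[(mask_data,) + tuple(idx)] = 1.0
    w = np.where(onehot == 1.0, 0.0, w)
    w_sum = w.sum(axis=0)
    w_sum[w_sum == 0] = 1.0
    probs = onehot * fidelity + (1.0 - fidelity) * w / w_sum
    return probs


def simulate_predictions(masks: dict[str, LabelMask], fidelity: float,
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Oracle classifier outputs for the four label masks.

    Returns ``ca`` — P(Calpha) per voxel; ``atom`` — (4, ...) class
    probabilities over {background, Calpha, N, C}; ``amino`` — (21, ...)
    over {background, 20 amino types}. With ``fidelity`` = 1 the per-voxel
    argmax of every volume equals the corresponding mask. Deterministic for
    a given seed.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError(f"fidelity {fidelity} outside [0, 1]")
    rng = np.random.default_rng(seed)
    atom = _class_probs(masks["atom"].data, 4, fidelity, rng)
    amino = _class_probs(masks["amino"].data, 21, fidelity, rng)
    ca2 = _class_probs(masks["ca"].data, 2, fidelity, rng)
    return {"ca": ca2[1], "atom": atom, "amino": amino}


def true_ca_voxel_centers(structure: list[BackboneResidue],
                          grid: DensityGrid) -> np.ndarray:
    """Voxel-center coordinates of the true Calpha atoms on a grid
    (nearest-voxel assignment); the ground truth a perfect trace recovers."""
    from .labeler import index_to_coord

    centers = []
    for r in structure:
        if r.ca_xyz is None:
            continue
        ijk = coord_to_index(r.ca_xyz, grid.origin, grid.voxel_size, "nearest")
        centers.append(index_to_coord(ijk, grid.origin, grid.voxel_size))
    return np.asarray(centers)
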