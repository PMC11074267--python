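"""HMM-guided alignment of protein sequences to predicted Calpha voxels.

Candidate Calpha voxels (from any per-voxel classifier) become the hidden
states of an HMM. Each state emits amino-acid types with probabilities
given by the normalized geometric mean ``sqrt(a * b)`` of the predicted
per-state amino-acid probability ``a`` and the background frequency ``b``.
Transitions between states follow a Gaussian over the Euclidean distance
between the two candidates, centered on the canonical consecutive-Calpha
spacing mu = 3.8047 Angstrom with an effective standard deviation
sigma * Lambda = 0.036 * 10 = 0.36 Angstrom. Any state may start a chain,
with initial probability proportional to its emission of the first residue.

Decoding uses a *customized, injective* Viterbi: a state (a physical
Calpha position) may appear at most once along a path. The exact problem
is combinatorial, so decoding is a beam search over partial injective
paths; a brute-force enumeration oracle for small models lives in the test
suite. Chains are traced longest-first, and states consumed by one chain
are unavailable to later chains.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .labeler import CODE_TO_THREE, index_to_coord

N_AMINO = 20

#: canonical consecutive-Calpha distance (Angstrom)
DEFAULT_MU = 3.8047
#: base standard deviation and its tunable scaling factor
DEFAULT_SIGMA = 0.036
DEFAULT_LAMBDA = 10.0
#: transition support window (Angstrom); the Gaussian with effective SD
#: 0.36 A is negligible outside it and full connectivity would be quadratic
DEFAULT_NEIGHBOR_WINDOW = (2.0, 6.0)

LOG_ZERO = -np.inf


class EmptyCandidateError(ValueError):
    """No voxel survived the probability threshold."""


class DegenerateEmissionError(ValueError):
    """An emission vector has no probability mass."""


class InfeasibleAlignmentError(ValueError):
    """Sequence longer than the number of available states."""


class AlignmentError(RuntimeError):
    """Beam search found no complete injective path."""


@dataclass
class CaCandidate:
    ijk: tuple[int, int, int]
    xyz: tuple[float, float, float]
    p_ca: float
    amino_probs: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_ca <= 1.0:
            raise ValueError(f"p_ca {self.p_ca} outside [0, 1]")
        self.amino_probs = np.asarray(self.amino_probs, dtype=np.float64)
        if self.amino_probs.shape != (N_AMINO,) or (self.amino_probs < 0).any():
            raise ValueError("amino_probs must be 20 nonnegative values")


@dataclass
class HmmModel:
    """HMM over Calpha candidates.

    ``emissions[s]`` is the normalized geometric-mean emission vector of
    state ``s``; ``log_trans`` holds per-state normalized log transition
    probabilities over the neighbor lists in ``neighbors``.
    """

    candidates: list[CaCandidate]
    emissions: np.ndarray
    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA
    lambda_scale: float = DEFAULT_LAMBDA
    background: np.ndarray = field(
        default_factory=lambda: np.full(N_AMINO, 1.0 / N_AMINO))
    neighbor_window: tuple[float, float] = DEFAULT_NEIGHBOR_WINDOW
    neighbors: list[np.ndarray] = field(default_factory=list)
    log_trans: list[np.ndarray] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.candidates)

    @property
    def effective_sd(self) -> float:
        return self.sigma * self.lambda_scale

    @property
    def coords(self) -> np.ndarray:
        return np.array([c.xyz for c in self.candidates])


@dataclass
class TracedChain:
    chain_id: str
    sequence: list[int]  # amino codes 1..20
    state_path: list[int]
    coords: np.ndarray
    log_score: float

    def __post_init__(self) -> None:
        if len(set(self.state_path)) != len(self.state_path):
            raise ValueError("state path must be injective")
        if len(self.state_path) != len(self.sequence):
            raise ValueError("path length must equal sequence length")


def extract_candidates(ca_prob, amino_prob, voxel_size, origin,
                       threshold: float = 0.5) -> list[CaCandidate]:
    """Threshold a Calpha probability volume into candidate states.

    Parameters
    ----------
    ca_prob : ndarray (nz, ny, nx)
        Per-voxel probability of holding a Calpha.
    amino_prob : ndarray (21, nz, ny, nx)
        Per-voxel class probabilities; class 0 is background/unknown and is
        discarded, classes 1..20 are renormalized into the candidate's
        20-vector.
    threshold : float in (0, 1)
        Candidates are voxels with ``p_ca >= threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    ca_prob = np.asarray(ca_prob)
    amino_prob = np.asarray(amino_prob)
    if amino_prob.shape != (N_AMINO + 1,) + ca_prob.shape:
        raise ValueError("amino_prob must have shape (21,) + ca_prob.shape")
    idx = np.argwhere(ca_prob >= threshold)
    if idx.size == 0:
        raise EmptyCandidateError(
            f"no voxel reaches the candidate threshold {threshold}")
    candidates = []
    for i, j, k in idx:
        probs = amino_prob[1:, i, j, k].astype(np.float64)
        total = probs.sum()
        probs = probs / total if total > 0 else np.full(N_AMINO, 1.0 / N_AMINO)
        candidates.append(CaCandidate(
            ijk=(int(i), int(j), int(k)),
            xyz=index_to_coord((int(i), int(j), int(k)), origin, voxel_size),
            p_ca=float(ca_prob[i, j, k]),
            amino_probs=probs,
        ))
    return candidates


def emission_probs(amino_probs, background) -> np.ndarray:
    """Normalized geometric mean sqrt(p * bg) of prediction and background."""
    p = np.asarray(amino_probs, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if (p < 0).any() or (bg < 0).any():
        raise ValueError("probabilities must be nonnegative")
    geo = np.sqrt(p * bg)
    total = geo.sum()
    if total <= 0:
        raise DegenerateEmissionError("all geometric-mean emissions are zero")
    return geo / total


def transition_weight(distance, model: HmmModel):
    """Unnormalized transition weight: Gaussian density at the given
    inter-candidate distance, mean ``mu``, SD ``sigma * lambda_scale``."""
    d = np.asarray(distance, dtype=np.float64)
    sd = model.effective_sd
    return np.exp(-0.5 * ((d - model.mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def build_hmm(candidates: list[CaCandidate],
              background=None,
              mu: float = DEFAULT_MU,
              sigma: float = DEFAULT_SIGMA,
              lambda_scale: float = DEFAULT_LAMBDA,
              neighbor_window: tuple[float, float] = DEFAULT_NEIGHBOR_WINDOW,
              ) -> HmmModel:
    """Assemble the HMM: emissions, neighbor lists and normalized transitions.

    Each state's outgoing transition distribution is the Gaussian weight over
    its neighbors within ``neighbor_window`` distance, renormalized to sum
    to one; states beyond the window are unreachable in one step.
    """
    if not candidates:
        raise EmptyCandidateError("cannot build an HMM with no states")
    if background is None:
        background = np.full(N_AMINO, 1.0 / N_AMINO)
    background = np.asarray(background, dtype=np.float64)
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")

    emissions = np.array([emission_probs(c.amino_probs, background)
                          for c in candidates])
    model = HmmModel(candidates=candidates, emissions=emissions, mu=mu,
                     sigma=sigma, lambda_scale=lambda_scale,
                     background=background, neighbor_window=neighbor_window)

    coords = model.coords
    lo, hi = neighbor_window
    tree = cKDTree(coords)
    pairs_per_state = tree.query_ball_tree(tree, r=hi)
    neighbors, log_trans = [], []
    for s, nbrs in enumerate(pairs_per_state):
        nbrs = np.array([t for t in nbrs if t != s], dtype=np.intp)
        if nbrs.size:
            dist = np.linalg.norm(coords[nbrs] - coords[s], axis=1)
            keep = dist >= lo
            nbrs, dist = nbrs[keep], dist[keep]
        if nbrs.size:
            w = transition_weight(dist, model)
            total = w.sum()
            if total > 0:
                logp = np.log(w / total)
            else:
                # all weights underflowed: fall back to relative log weights
                logq = -0.5 * ((dist - mu) / model.effective_sd) ** 2
                logp = logq - _logsumexp(logq)
            order = np.argsort(nbrs)
            neighbors.append(nbrs[order])
            log_trans.append(logp[order])
        else:
            neighbors.append(nbrs)
            log_trans.append(np.empty(0))
    model.neighbors = neighbors
    model.log_trans = log_trans
    return model


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))


def initial_probs(model: HmmModel, first_aa: int,
                  available=None) -> np.ndarray:
    """Per-state start probabilities: emission of the first residue,
    normalized over (available) states. ``first_aa`` is an amino code 1..20."""
    if model.n_states == 0:
        raise EmptyCandidateError("model has no states")
    e = model.emissions[:, first_aa - 1].copy()
    if available is not None:
        mask = np.zeros(model.n_states, dtype=bool)
        mask[list(available)] = True
        e = np.where(mask, e, 0.0)
    total = e.sum()
    if total <= 0:
        raise DegenerateEmissionError(
            "no state can emit the first residue of the chain")
    return e / total


def _beam_decode(model: HmmModel, seq: list[int], available: set[int],
                 beam_width: int) -> tuple[list[int], float]:
    """Highest-scoring injective path through ``available`` states emitting
    ``seq``, found by beam search over partial paths.

    Score = log pi(s1) + sum log emission + sum log transition (the first
    emission appears both inside pi and in the emission sum, matching the
    enumeration oracle). Ties break toward the lexicographically smallest
    state path.
    """
    log_e = np.log(np.where(model.emissions > 0, model.emissions, np.nan))
    log_e = np.where(np.isnan(log_e), LOG_ZERO, log_e)

    pi = initial_probs(model, seq[0], available=available)
    beam: list[tuple[float, tuple[int, ...]]] = []
    for s in sorted(available):
        if pi[s] <= 0:
            continue
        score = float(np.log(pi[s]) + log_e[s, seq[0] - 1])
        if np.isfinite(score):
            beam.append((score, (s,)))
    beam = heapq.nlargest(beam_width, beam, key=lambda x: (x[0], _neg_path(x[1])))
    if not beam:
        raise AlignmentError("no available state can start the chain")

    for pos in range(1, len(seq)):
        aa = seq[pos]
        extensions: list[tuple[float, tuple[int, ...]]] = []
        for score, path in beam:
            s = path[-1]
            used = set(path)
            for t, logp in zip(model.neighbors[s], model.log_trans[s]):
                t = int(t)
                if t not in available or t in used:
                    continue
                e = log_e[t, aa - 1]
                if not np.isfinite(e) or not np.isfinite(logp):
                    continue
                extensions.append((score + logp + e, path + (t,)))
        if not extensions:
            raise AlignmentError(
                f"beam search dead-ended at residue {pos + 1} of {len(seq)}; "
                f"try a larger beam width or candidate threshold")
        beam = heapq.nlargest(beam_width, extensions,
                              key=lambda x: (x[0], _neg_path(x[1])))

    best_score, best_path = max(beam, key=lambda x: (x[0], _neg_path(x[1])))
    return list(best_path), best_score


def _neg_path(path: tuple[int, ...]) -> tuple[int, ...]:
    # for max(): prefer lexicographically smaller paths on score ties
    return tuple(-p for p in path)


def viterbi_align(model: HmmModel, sequences: dict[str, list[int]],
                  beam_width: int = 32) -> list[TracedChain]:
    """Trace every chain through the model with the injective beam Viterbi.

    ``sequences`` maps chain id to a list of amino codes (1..20). Chains
    are processed longest first; states consumed by one chain are removed
    from the pool before the next is traced.

    Raises
    ------
    InfeasibleAlignmentError
        If a chain is longer than the states still available.
    ValueError
        If any sequence is empty.
    """
    for cid, seq in sequences.items():
        if not seq:
            raise ValueError(f"chain {cid!r} has an empty sequence")
    total = sum(len(s) for s in sequences.values())
    if total > model.n_states:
        raise InfeasibleAlignmentError(
            f"{total} residues requested but only {model.n_states} states")

    available = set(range(model.n_states))
    coords = model.coords
    traced: list[TracedChain] = []
    for cid in sorted(sequences, key=lambda c: (-len(sequences[c]), c)):
        seq = list(sequences[cid])
        if len(seq) > len(available):
            raise InfeasibleAlignmentError(
                f"chain {cid!r} needs {len(seq)} states, "
                f"{len(available)} remain")
        path, score = _beam_decode(model, seq, available, beam_width)
        available.difference_update(path)
        traced.append(TracedChain(
            chain_id=cid,
            sequence=seq,
            state_path=path,
            coords=coords[path],
            log_score=score,
        ))
    return traced


def write_backbone_pdb(chains: list[TracedChain], path) -> None:
    """Write traced chains as a Calpha-only PDB file (one ATOM per residue)."""
    lines = []
    serial = 1
    for chain in chains:
        for n, (aa, xyz) in enumerate(zip(chain.sequence, chain.coords), 1):
            resname = CODE_TO_THREE.get(aa, "UNK")
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname:<3s} {chain.chain_id[:1]}"
                f"{n:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
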