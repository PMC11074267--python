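"""HMM construction, emissions, transitions and the injective Viterbi.

The beam decoder is checked against a brute-force oracle that enumerates
every injective state sequence and scores it with the same log-domain
formula (log initial + sum log emission + sum log transition).
"""

import itertools

import numpy as np
import pytest

from mapforge.hmmtrace import (
    DEFAULT_MU,
    AlignmentError,
    CaCandidate,
    EmptyCandidateError,
    HmmModel,
    InfeasibleAlignmentError,
    build_hmm,
    emission_probs,
    extract_candidates,
    initial_probs,
    transition_weight,
    viterbi_align,
    write_backbone_pdb,
)


def make_candidates(coords, amino_probs):
    return [
        CaCandidate(ijk=(0, 0, n), xyz=tuple(map(float, c)), p_ca=1.0,
                    amino_probs=np.asarray(p, dtype=float))
        for n, (c, p) in enumerate(zip(coords, amino_probs))
    ]


def sharp(aa_code, eps=1e-3):
    p = np.full(20, eps)
    p[aa_code - 1] = 1.0
    return p / p.sum()


def brute_force_align(model, seq):
    """Exhaustive enumeration oracle over all injective state paths."""
    trans = [dict(zip(map(int, nb), lt))
             for nb, lt in zip(model.neighbors, model.log_trans)]
    log_e = np.where(model.emissions > 0, np.log(model.emissions), -np.inf)
    try:
        pi = initial_probs(model, seq[0])
    except Exception:
        return None
    best = None
    for path in itertools.permutations(range(model.n_states), len(seq)):
        if pi[path[0]] <= 0:
            continue
        score = np.log(pi[path[0]]) + log_e[path[0], seq[0] - 1]
        for pos in range(1, len(seq)):
            step = trans[path[pos - 1]].get(path[pos], -np.inf)
            score += step + log_e[path[pos], seq[pos] - 1]
            if not np.isfinite(score):
                break
        if not np.isfinite(score):
            continue
        key = (score, tuple(-s for s in path))
        if best is None or key > best[0]:
            best = (key, list(path), score)
    if best is None:
        return None
    return best[1], best[2]


class TestEmissions:
    def test_uniform_times_uniform_is_uniform(self):
        e = emission_probs(np.full(20, 0.05), np.full(20, 0.05))
        np.testing.assert_allclose(e, 0.05)

    def test_zeros_preserved(self):
        p = np.zeros(20)
        p[0] = 1.0
        e = emission_probs(p, np.full(20, 0.05))
        assert e[0] == 1.0 and (e[1:] == 0).all()

    def test_hand_worked_ratio(self):
        """sqrt(0.8*0.5) : sqrt(0.2*0.5) = 2 : 1 -> (2/3, 1/3)."""
        p = np.zeros(20)
        p[:2] = (0.8, 0.2)
        bg = np.zeros(20)
        bg[:2] = 0.5
        e = emission_probs(p, bg)
        np.testing.assert_allclose(e[:2], [2 / 3, 1 / 3], rtol=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(20)
            bg = rng.dirichlet(np.ones(20))
            assert emission_probs(p, bg).sum() == pytest.approx(1.0)


class TestTransitions:
    @pytest.fixture
    def model(self):
        cands = make_candidates([(0, 0, 0)], [np.full(20, 0.05)])
        return build_hmm(cands)

    def test_maximized_at_canonical_spacing(self, model):
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda d: -transition_weight(d, model),
                              bounds=(2.0, 6.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x == pytest.approx(DEFAULT_MU, abs=1e-6)

    def test_symmetry_about_mean(self, model):
        for delta in (0.1, 0.36, 1.0):
            assert transition_weight(DEFAULT_MU + delta, model) == \
                pytest.approx(transition_weight(DEFAULT_MU - delta, model))

    def test_one_sd_ratio(self, model):
        """Gaussian falls by exp(1/2) one standard deviation from the mean."""
        ratio = (transition_weight(DEFAULT_MU, model)
                 / transition_weight(DEFAULT_MU + 0.36, model))
        assert ratio == pytest.approx(np.exp(0.5), rel=1e-9)

    def test_outgoing_transitions_normalized(self):
        rng = np.random.default_rng(1)
        coords = rng.random((8, 3)) * 8
        cands = make_candidates(coords, [np.full(20, 0.05)] * 8)
        model = build_hmm(cands)
        for nbrs, logp in zip(model.neighbors, model.log_trans):
            if len(nbrs):
                assert np.exp(logp).sum() == pytest.approx(1.0)


class TestInitialProbs:
    def test_identical_emissions_give_uniform(self):
        cands = make_candidates([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)],
                                [np.full(20, 0.05)] * 3)
        model = build_hmm(cands)
        np.testing.assert_allclose(initial_probs(model, 5), 1 / 3)

    def test_hand_worked_two_state(self):
        """Emission 0.2 and 0.6 of the first residue -> pi = (0.25, 0.75)."""
        e = np.array([[0.2, 0.8] + [0.0] * 18,
                      [0.6, 0.4] + [0.0] * 18])
        cands = make_candidates([(0, 0, 0), (3.8, 0, 0)], e)
        model = build_hmm(cands)
        model.emissions = e  # bypass geometric-mean reweighting
        np.testing.assert_allclose(initial_probs(model, 1), [0.25, 0.75])

    def test_sums_to_one(self):
        rng = np.random.default_rng(2)
        cands = make_candidates(rng.random((6, 3)) * 10,
                                rng.random((6, 20)))
        model = build_hmm(cands)
        for aa in (1, 7, 20):
            assert initial_probs(model, aa).sum() == pytest.approx(1.0)


class TestExtractCandidates:
    def _volumes(self):
        ca = np.zeros((4, 4, 4))
        ca[1, 2, 3] = 1.0
        ca[2, 2, 2] = 0.9
        amino = np.full((21, 4, 4, 4), 1 / 21)
        return ca, amino

    def test_thresholding(self):
        ca, amino = self._volumes()
        cands = extract_candidates(ca, amino, (1, 1, 1), (0, 0, 0), 0.5)
        assert {c.ijk for c in cands} == {(1, 2, 3), (2, 2, 2)}
        # xyz follows the index-to-coordinate transform
        assert cands[0].xyz == (3.0, 2.0, 1.0)

    def test_amino_probs_renormalized_over_20(self):
        ca, amino = self._volumes()
        cands = extract_candidates(ca, amino, (1, 1, 1), (0, 0, 0), 0.5)
        for c in cands:
            assert c.amino_probs.sum() == pytest.approx(1.0)
            assert len(c.amino_probs) == 20

    def test_bad_threshold(self):
        ca, amino = self._volumes()
        with pytest.raises(ValueError):
            extract_candidates(ca, amino, (1, 1, 1), (0, 0, 0), 1.1)

    def test_no_survivor_raises(self):
        ca, amino = self._volumes()
        with pytest.raises(EmptyCandidateError):
            extract_candidates(ca * 0.3, amino, (1, 1, 1), (0, 0, 0), 0.5)


class TestViterbi:
    def test_three_state_chain_recovered(self):
        """States favoring G, A, V in a line; sequence GAV takes them in
        order (verified against enumeration of all 6 injective orderings)."""
        coords = [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)]
        cands = make_candidates(coords, [sharp(8), sharp(1), sharp(20)])
        model = build_hmm(cands)
        seq = [8, 1, 20]  # G, A, V
        chains = viterbi_align(model, {"A": seq}, beam_width=720)
        assert chains[0].state_path == [0, 1, 2]
        oracle = brute_force_align(model, seq)
        assert oracle[0] == [0, 1, 2]
        assert chains[0].log_score == pytest.approx(oracle[1])

    def test_single_state_single_residue(self):
        cands = make_candidates([(0, 0, 0)], [sharp(3)])
        model = build_hmm(cands)
        chains = viterbi_align(model, {"A": [3]}, beam_width=4)
        pi = initial_probs(model, 3)
        expected = np.log(pi[0]) + np.log(model.emissions[0, 2])
        assert chains[0].log_score == pytest.approx(expected)

    def test_injectivity_makes_long_sequences_infeasible(self):
        cands = make_candidates([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)],
                                [np.full(20, 0.05)] * 3)
        model = build_hmm(cands)
        with pytest.raises(InfeasibleAlignmentError):
            viterbi_align(model, {"A": [1, 2, 3, 4]}, beam_width=8)

    def test_empty_sequence_rejected(self):
        cands = make_candidates([(0, 0, 0)], [sharp(1)])
        model = build_hmm(cands)
        with pytest.raises(ValueError):
            viterbi_align(model, {"A": []})

    def test_multi_chain_global_state_consumption(self):
        """Two chains cannot share a state; longest chain is traced first."""
        coords = [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0), (30, 0, 0), (33.8, 0, 0)]
        probs = [sharp(1), sharp(2), sharp(3), sharp(1), sharp(2)]
        model = build_hmm(make_candidates(coords, probs))
        chains = viterbi_align(model, {"long": [1, 2, 3], "short": [1, 2]},
                               beam_width=64)
        by_id = {c.chain_id: c for c in chains}
        assert by_id["long"].state_path == [0, 1, 2]
        assert by_id["short"].state_path == [3, 4]
        used = [s for c in chains for s in c.state_path]
        assert len(used) == len(set(used))

    @pytest.mark.parametrize("trial", range(40))
    def test_beam_equals_brute_force_on_small_models(self, trial):
        """With a beam at least as wide as the path count, beam search is
        exhaustive and must match enumeration exactly."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 7))
        coords = rng.random((n, 3)) * rng.uniform(3, 8)
        probs = rng.dirichlet(np.ones(20), size=n)
        model = build_hmm(make_candidates(coords, probs))
        seq_len = int(rng.integers(1, n + 1))
        seq = [int(a) for a in rng.integers(1, 21, size=seq_len)]
        oracle = brute_force_align(model, seq)
        try:
            chains = viterbi_align(model, {"A": seq}, beam_width=5040)
        except AlignmentError:
            assert oracle is None
            return
        assert oracle is not None
        assert chains[0].state_path == oracle[0]
        assert chains[0].log_score == pytest.approx(oracle[1])

    def test_no_underflow_on_long_chains(self):
        """Log-domain scores stay finite for thousands of residues."""
        n = 2000
        coords = [(3.8 * i, 0.0, 0.0) for i in range(n)]
        probs = [np.full(20, 0.05)] * n
        model = build_hmm(make_candidates(coords, probs))
        seq = [int(a) for a in np.random.default_rng(0).integers(1, 21, n)]
        chains = viterbi_align(model, {"A": seq}, beam_width=2)
        assert np.isfinite(chains[0].log_score)


class TestBackbonePdb:
    def test_round_trip_through_parser(self, tmp_path):
        from mapforge.hmmtrace import TracedChain
        from mapforge.labeler import parse_structure

        coords = np.array([[1.0, 2.0, 3.0], [4.5, 2.0, 3.0], [8.0, 2.5, 3.5]])
        chain = TracedChain(chain_id="A", sequence=[1, 8, 20],
                            state_path=[2, 0, 1], coords=coords,
                            log_score=-1.0)
        path = tmp_path / "traced.pdb"
        write_backbone_pdb([chain], path)
        residues, seqs = parse_structure(path)
        assert [r.amino_code for r in residues] == [1, 8, 20]
        np.testing.assert_allclose([r.ca_xyz for r in residues], coords)
        assert seqs == {"A": "AGV"}

    def test_empty_chain_list(self, tmp_path):
        path = tmp_path / "empty.pdb"
        write_backbone_pdb([], path)
        assert path.read_text().strip() == "END"

    def test_atom_record_count(self, tmp_path):
        from mapforge.hmmtrace import TracedChain
        chain = TracedChain(chain_id="B", sequence=[5, 5, 5],
                            state_path=[0, 1, 2],
                            coords=np.zeros((3, 3)), log_score=0.0)
        path = tmp_path / "three.pdb"
        write_backbone_pdb([chain], path)
        atoms = [ln for ln in path.read_text().splitlines()
                 if ln.startswith("ATOM")]
        assert len(atoms) == 3
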