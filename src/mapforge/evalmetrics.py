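"""Evaluation metrics and dataset bookkeeping.

Voxel level: precision / recall / F1 of thresholded Calpha predictions
against a label mask. Chain level: comparison of a traced backbone with a
reference structure — RMSD over matched Calpha pairs, the percentage of
reference residues matched within a distance cutoff, and the sequence
identity among matches (the conventions of chain-comparison tools used in
map-to-model evaluation). Dataset level: resolution-bin statistics and the
seeded 90/10 train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .labeler import BackboneResidue


@dataclass
class ChainComparisonReport:
    rmsd: float
    matching_pct: float
    seq_id_pct: float
    n_reference: int
    n_matched: int


@dataclass
class SplitSpec:
    train_ids: list
    validation_ids: list
    train_fraction: float
    seed: int


def voxel_f1(predicted_prob, truth, threshold: float = 0.5):
    """Precision, recall and F1 of ``predicted_prob >= threshold`` against a
    binary (or binarizable) truth mask. Vanishing denominators yield 0."""
    pred = np.asarray(predicted_prob)
    truth_data = np.asarray(truth.data if hasattr(truth, "scheme") else truth)
    if pred.shape != truth_data.shape:
        raise ValueError(
            f"shape mismatch: prediction {pred.shape} vs truth {truth_data.shape}")
    pos = pred >= threshold
    true = truth_data != 0
    tp = int(np.sum(pos & true))
    fp = int(np.sum(pos & ~true))
    fn = int(np.sum(~pos & true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _ca_array(residues: list[BackboneResidue]):
    coords, codes = [], []
    for r in residues:
        if r.ca_xyz is not None:
            coords.append(r.ca_xyz)
            codes.append(r.amino_code)
    return np.asarray(coords, dtype=float), np.asarray(codes)


def chain_compare(model: list[BackboneResidue],
                  reference: list[BackboneResidue],
                  match_cutoff: float = 3.0) -> ChainComparisonReport:
    """Compare a traced backbone against a reference structure.

    Calpha atoms are matched one-to-one, globally nearest pair first, under
    the distance cutoff. ``matching_pct`` is the percentage of *reference*
    residues matched; ``seq_id_pct`` the percentage of matched pairs with
    identical amino type; ``rmsd`` is over matched pairs (0 when nothing
    matches).
    """
    m_xyz, m_code = _ca_array(model)
    r_xyz, r_code = _ca_array(reference)
    if len(m_xyz) == 0 or len(r_xyz) == 0:
        raise ValueError("both structures need at least one Calpha atom")

    tree = cKDTree(r_xyz)
    pairs = []
    for a, nbrs in enumerate(tree.query_ball_point(m_xyz, match_cutoff)):
        for t in nbrs:
            pairs.append((float(np.linalg.norm(m_xyz[a] - r_xyz[t])), a, t))
    pairs.sort()
    used_m, used_r = set(), set()
    sq_sum = 0.0
    n_matched = 0
    n_same = 0
    for d, a, t in pairs:
        if a in used_m or t in used_r:
            continue
        used_m.add(a)
        used_r.add(t)
        n_matched += 1
        sq_sum += d * d
        if m_code[a] == r_code[t]:
            n_same += 1
    rmsd = float(np.sqrt(sq_sum / n_matched)) if n_matched else 0.0
    return ChainComparisonReport(
        rmsd=rmsd,
        matching_pct=100.0 * n_matched / len(r_xyz),
        seq_id_pct=100.0 * n_same / n_matched if n_matched else 0.0,
        n_reference=len(r_xyz),
        n_matched=n_matched,
    )


def summarize_reports(records) -> pd.Series:
    """Arithmetic column means of per-structure evaluation rows.

    ``records`` is anything ``pandas.DataFrame`` accepts (list of dicts,
    DataFrame, ...); non-numeric columns are ignored.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("need at least one record")
    return df.mean(numeric_only=True)


RESOLUTION_BINS = ((1.0, 2.0), (2.0, 3.0), (3.0, 4.0))


def _round_half_up(x: float, decimals: int = 2) -> float:
    scale = 10 ** decimals
    return float(np.floor(x * scale + 0.5) / scale)


def dataset_stats(metadata) -> pd.DataFrame:
    """Per-resolution-bin counts and percentages.

    ``metadata`` must provide a ``resolution`` column (Angstrom, within
    [1, 4]). Bins are [1,2), [2,3), [3,4]; percentages are rounded half-up
    to two decimals.
    """
    df = pd.DataFrame(metadata)
    res = df["resolution"].astype(float)
    if ((res < 1.0) | (res > 4.0)).any():
        raise ValueError("resolutions must lie within [1, 4] Angstrom")
    rows = []
    total = len(res)
    for n, (lo, hi) in enumerate(RESOLUTION_BINS):
        last = n == len(RESOLUTION_BINS) - 1
        in_bin = (res >= lo) & ((res <= hi) if last else (res < hi))
        count = int(in_bin.sum())
        rows.append({
            "bin": f"{lo:.1f}-{hi:.1f}",
            "count": count,
            "percent": _round_half_up(100.0 * count / total),
        })
    return pd.DataFrame(rows)


def split_dataset(ids, train_fraction: float = 0.9, seed: int = 0,
                  resolutions=None) -> SplitSpec:
    """Seeded shuffle split into train / validation.

    ``train size = floor(train_fraction * n)``; the remainder validates.
    When ``resolutions`` is given (one per id), the split is stratified
    within each resolution bin so both sets keep the bin distribution.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1]")
    ids = list(ids)
    rng = np.random.default_rng(seed)

    def _split(sub_ids):
        order = rng.permutation(len(sub_ids))
        n_train = int(np.floor(train_fraction * len(sub_ids)))
        train = [sub_ids[i] for i in order[:n_train]]
        val = [sub_ids[i] for i in order[n_train:]]
        return train, val

    if resolutions is None:
        train, val = _split(ids)
    else:
        res = np.asarray(list(resolutions), dtype=float)
        train, val = [], []
        for n, (lo, hi) in enumerate(RESOLUTION_BINS):
            last = n == len(RESOLUTION_BINS) - 1
            in_bin = (res >= lo) & ((res <= hi) if last else (res < hi))
            sub = [i for i, keep in zip(ids, in_bin) if keep]
            t, v = _split(sub)
            train += t
            val += v
    return SplitSpec(train_ids=train, validation_ids=val,
                     train_fraction=train_fraction, seed=seed)
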