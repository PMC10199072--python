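"""Library characterization: descriptors, KL divergence, recovery, embedding.

Distribution comparison follows the convention that P is the reference
(known natural products) and Q the candidate (generated) distribution, with
D_KL(P||Q) = sum_x P(x) ln(P(x)/Q(x)) in nats, summed over P's support.
Continuous properties are discretized on a fixed-width grid (default width
0.1) anchored at 0; categorical properties (e.g. biosynthetic pathway
labels, including "none") use the union of observed labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy.special import rel_entr
from sklearn.manifold import TSNE

log = logging.getLogger(__name__)

# the 10-descriptor panel used for distribution comparison and embedding
PANEL10 = (
    "NumAromaticRings", "NumAliphaticRings", "MolLogP", "MolWt",
    "NumHDonors", "NumHAcceptors", "NumHeteroatoms", "TPSA",
    "NumRotatableBonds", "NumValenceElectrons",
)

# the 27-descriptor annotation panel carried on each record
PANEL27 = (
    "BalabanJ", "BertzCT", "NumAromaticRings", "HallKierAlpha", "Kappa1",
    "Chi0", "Chi0n", "Chi0v", "MolLogP", "MolMR", "MolWt", "ExactMolWt",
    "HeavyAtomCount", "HeavyAtomMolWt", "NHOHCount", "NOCount",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "RingCount",
    "FractionCSP3", "TPSA", "LabuteASA", "NumRotatableBonds",
    "NumValenceElectrons", "NumSaturatedRings", "NumAliphaticRings",
)

_DESCRIPTOR_FN = {name: fn for name, fn in Descriptors.descList}


def compute_descriptors(molecule, panel: str = "panel10") -> dict[str, float]:
    """Named molecular descriptors (standard definitions); deterministic."""
    names = PANEL10 if panel == "panel10" else PANEL27
    if isinstance(molecule, str):
        molecule = Chem.MolFromSmiles(molecule)
        if molecule is None:
            raise ValueError("unparseable SMILES")
    return {name: float(_DESCRIPTOR_FN[name](molecule)) for name in names}


@dataclass(frozen=True)
class DistributionPair:
    """Aligned reference (P) and candidate (Q) distributions on one support."""

    support: tuple
    p: np.ndarray
    q: np.ndarray
    p_counts: np.ndarray = field(default=None, compare=False)
    q_counts: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        if abs(self.p.sum() - 1) > 1e-9 or abs(self.q.sum() - 1) > 1e-9:
            raise ValueError("distributions must be normalized")
        if (self.p < 0).any() or (self.q < 0).any():
            raise ValueError("probabilities must be non-negative")


def make_distribution(values_ref, values_cand, bin_width: float | None = 0.1,
                      categorical: bool = False) -> DistributionPair:
    """Bin two value lists on a common support and normalize.

    Continuous values fall into bins ``[k*w, (k+1)*w)`` anchored at 0;
    categorical values are mapped over the union of observed labels.
    """
    if len(values_ref) == 0 or len(values_cand) == 0:
        raise ValueError("empty inputs")
    if categorical:
        labels = sorted(set(values_ref) | set(values_cand))
        idx = {lab: i for i, lab in enumerate(labels)}
        pc = np.bincount([idx[v] for v in values_ref], minlength=len(labels))
        qc = np.bincount([idx[v] for v in values_cand], minlength=len(labels))
        support = tuple(labels)
    else:
        r = np.floor(np.asarray(values_ref, dtype=float) / bin_width).astype(int)
        c = np.floor(np.asarray(values_cand, dtype=float) / bin_width).astype(int)
        lo = min(r.min(), c.min())
        hi = max(r.max(), c.max())
        pc = np.bincount(r - lo, minlength=hi - lo + 1)
        qc = np.bincount(c - lo, minlength=hi - lo + 1)
        support = tuple((k + lo) * bin_width for k in range(hi - lo + 1))
    return DistributionPair(support, pc / pc.sum(), qc / qc.sum(), pc, qc)


def kl_divergence(pair: DistributionPair) -> float:
    """D_KL(P||Q) in nats over P's support.

    When Q assigns zero probability inside P's support the ratio is
    undefined; in that case one pseudo-count is added to every Q bin within
    P's support and Q is renormalized before summation (a smoothing needed
    only at desk-scale sample sizes; with no empty in-support bins the
    plain summation is returned).
    """
    in_support = pair.p > 0
    q = pair.q.astype(float).copy()
    if np.any(q[in_support] == 0):
        if pair.q_counts is not None:
            qc = pair.q_counts.astype(float).copy()
        else:
            qc = q
        qc[in_support] += 1
        q = qc / qc.sum()
    p = pair.p[in_support]
    return float(rel_entr(p, q[in_support]).sum())


def recovery_rate(generated_canonical: set[str], heldout_canonical: set[str]) -> float:
    """Fraction of the held-out canonical set reproduced among generated."""
    if not heldout_canonical:
        raise ValueError("empty held-out set")
    return len(set(generated_canonical) & set(heldout_canonical)) / len(heldout_canonical)


@dataclass(frozen=True)
class Embedding2D:
    coordinates: np.ndarray
    params: dict


def standardize_columns(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Z-score each column; constant columns are dropped with a warning."""
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=0)
    keep = [int(j) for j in np.where(sd > 0)[0]]
    if len(keep) < matrix.shape[1]:
        warnings.warn(f"dropping {matrix.shape[1] - len(keep)} constant column(s)")
    sub = matrix[:, keep]
    return (sub - sub.mean(axis=0)) / sub.std(axis=0), keep


def embed_2d(descriptor_matrix: np.ndarray, random_state: int = 7,
             perplexity: float = 30.0) -> Embedding2D:
    """t-SNE projection of a z-scored descriptor matrix to 2-D.

    Uses ``n_components=2, init="pca"`` and the given ``random_state``;
    deterministic for a fixed seed.
    """
    z, kept = standardize_columns(descriptor_matrix)
    if z.shape[0] < 2 * perplexity + 2:
        raise ValueError(
            f"need at least {int(2 * perplexity + 2)} rows for perplexity {perplexity}")
    tsne = TSNE(n_components=2, init="pca", random_state=random_state,
                perplexity=perplexity)
    coords = tsne.fit_transform(z)
    return Embedding2D(coords, {
        "n_components": 2, "init": "pca", "random_state": random_state,
        "perplexity": perplexity, "columns_kept": kept,
    })


def density_grid(embedding: Embedding2D, bins: int = 50) -> np.ndarray:
    """Point counts on a ``bins`` x ``bins`` grid over the bounding box."""
    x, y = embedding.coordinates[:, 0], embedding.coordinates[:, 1]
    hist, _, _ = np.histogram2d(x, y, bins=bins)
    return hist
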