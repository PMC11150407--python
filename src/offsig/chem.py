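"""Compound fingerprints, Tanimoto similarity, beta nulls, hit clustering.

Hit compounds are fingerprinted (Morgan/circular bits via RDKit when
available, otherwise a deterministic substring-hash fallback over the
canonicalized SMILES text), all pairwise Tanimoto similarities are computed,
and a beta distribution is fitted to the similarity scores conditioned on
set-bit counts to give an upper-tail p-value per pair.  The similarity
matrix's rows are then clustered by average-linkage agglomeration on
Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

try:  # optional cheminformatics toolkit
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.*")
    HAVE_RDKIT = True
except ImportError:  # pragma: no cover - rdkit present in dev env
    HAVE_RDKIT = False

EPS_CLAMP = 1e-6


@dataclass
class Fingerprint:
    compound_id: str
    n_bits: int
    set_bits: np.ndarray  # sorted unique indices < n_bits
    source: str  # toolkit | fallback | provided

    def __post_init__(self) -> None:
        bits = np.unique(np.asarray(self.set_bits, dtype=int))
        if bits.size and (bits[0] < 0 or bits[-1] >= self.n_bits):
            raise ValueError("set bit index out of range")
        self.set_bits = bits

    @property
    def n_set(self) -> int:
        return int(len(self.set_bits))


def _fallback_fingerprint(smiles: str, n_bits: int) -> np.ndarray:
    """Hash all substrings of length 1–7 of the SMILES into n_bits buckets.

    Deterministic (FNV-1a) so fingerprints are stable across runs and
    platforms; a coarse stand-in for substructure keys.
    """
    s = smiles.strip()
    bits = set()
    for ln in range(1, 8):
        for i in range(len(s) - ln + 1):
            h = 2166136261
            for ch in s[i:i + ln].encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
            bits.add(h % n_bits)
    return np.array(sorted(bits), dtype=int)


def fingerprint_compounds(
    smiles_map, n_bits: int = 1024, radius: int = 2, use_toolkit: bool | None = None
) -> list[Fingerprint]:
    """Fingerprint compounds from ``{compound_id: smiles}`` pairs.

    Uses RDKit Morgan bits when installed (``source='toolkit'``), else the
    deterministic substring-hash fallback.  Unparseable or empty SMILES are
    skipped with a warning.
    """
    if use_toolkit is None:
        use_toolkit = HAVE_RDKIT
    if use_toolkit and not HAVE_RDKIT:
        raise ImportError("rdkit is not installed; use_toolkit=False")
    gen = (rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                     fpSize=n_bits)
           if use_toolkit else None)
    out: list[Fingerprint] = []
    items = smiles_map.items() if hasattr(smiles_map, "items") else smiles_map
    for cid, smi in items:
        if not isinstance(smi, str) or not smi.strip():
            warnings.warn(f"compound {cid!r}: empty SMILES, skipped")
            continue
        if use_toolkit:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                warnings.warn(f"compound {cid!r}: unparseable SMILES, skipped")
                continue
            bv = gen.GetFingerprint(mol)
            bits = np.array(sorted(bv.GetOnBits()), dtype=int)
            out.append(Fingerprint(cid, n_bits, bits, "toolkit"))
        else:
            canon = smi.strip()
            out.append(Fingerprint(cid, n_bits,
                                   _fallback_fingerprint(canon, n_bits),
                                   "fallback"))
    return out


def tanimoto(a: Fingerprint, b: Fingerprint, empty_value: float = 1.0) -> float:
    """|A ∩ B| / |A ∪ B|; ``empty_value`` is returned when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    inter = np.intersect1d(a.set_bits, b.set_bits, assume_unique=True).size
    union = a.n_set + b.n_set - inter
    if union == 0:
        return empty_value
    return inter / union


def similarity_matrix(fps: list[Fingerprint]) -> pd.DataFrame:
    """Symmetric pairwise Tanimoto matrix (ids × ids)."""
    n = len(fps)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    ids = [f.compound_id for f in fps]
    return pd.DataFrame(m, index=ids, columns=ids)


@dataclass
class BetaNull:
    """Per-bin Beta(α, β) null for Tanimoto scores, binned on set-bit count."""

    bin_edges: np.ndarray           # right-open brackets over min pair bit count
    alpha: np.ndarray               # per-bin α (NaN = unfit)
    beta: np.ndarray                # per-bin β
    counts: np.ndarray              # scores per bin
    global_alpha: float = np.nan
    global_beta: float = np.nan

    def bin_of(self, n_set_min: int) -> int:
        idx = int(np.searchsorted(self.bin_edges, n_set_min, side="right") - 1)
        return int(np.clip(idx, 0, len(self.alpha) - 1))


def _beta_moments(x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta estimates; NaN when variance is degenerate."""
    m, v = float(np.mean(x)), float(np.var(x))
    if np.ptp(x) == 0 or v <= 0 or not 0 < m < 1:
        return np.nan, np.nan
    common = m * (1 - m) / v - 1
    if common <= 0:
        return np.nan, np.nan
    return m * common, (1 - m) * common


def fit_beta_null(
    scores, bit_counts, bin_width: int = 32, min_per_bin: int = 10
) -> BetaNull:
    """Fit per-bin method-of-moments Beta nulls to Tanimoto scores.

    ``bit_counts`` is the minimum set-bit count of each score's fingerprint
    pair; bins are right-open brackets of ``bin_width`` bits.  Scores are
    clamped into (ε, 1−ε).  Bins with fewer than ``min_per_bin`` usable
    scores, or degenerate variance, are marked unfit (NaN) and inherit the
    global fit at evaluation time.
    """
    scores = np.clip(np.asarray(scores, dtype=float), EPS_CLAMP, 1 - EPS_CLAMP)
    bits = np.asarray(bit_counts, dtype=int)
    if scores.shape != bits.shape:
        raise ValueError("scores and bit_counts must align")
    lo = (bits.min() // bin_width) * bin_width
    hi = (bits.max() // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    n_bins = len(edges) - 1
    a = np.full(n_bins, np.nan)
    b = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.clip(np.searchsorted(edges, bits, side="right") - 1, 0,
                    n_bins - 1)
    for k in range(n_bins):
        sub = scores[which == k]
        counts[k] = sub.size
        if sub.size >= min_per_bin:
            a[k], b[k] = _beta_moments(sub)
    ga, gb = _beta_moments(scores)
    return BetaNull(edges, a, b, counts, ga, gb)


def similarity_pvalue(
    score: float, n_set_min: int, null: BetaNull
) -> float:
    """Upper-tail probability of ``score`` under the bin's Beta null.

    Falls back to the global fit (with a warning) when the bin is unfit.
    """
    k = null.bin_of(n_set_min)
    a, b = null.alpha[k], null.beta[k]
    if np.isnan(a) or np.isnan(b):
        warnings.warn(
            f"beta-null bin {k} unfit; falling back to the global fit"
        )
        a, b = null.global_alpha, null.global_beta
    if np.isnan(a) or np.isnan(b):
        raise ValueError("no usable beta null (global fit degenerate)")
    s = float(np.clip(score, EPS_CLAMP, 1 - EPS_CLAMP))
    return float(stats.beta.sf(s, a, b))


def cluster_hits(
    similarity: pd.DataFrame | np.ndarray,
    cut_height: float | None = None,
    atol: float = 1e-9,
):
    """Average-linkage clustering of similarity-matrix rows.

    Distances are Euclidean between the matrix ROWS (similarity profiles),
    matching `hclust(dist(M), method="average")`.  Returns the merge table
    (scipy linkage format, heights non-decreasing) and, when ``cut_height``
    is given, flat labels from cutting the dendrogram at that height.
    """
    m = similarity.to_numpy() if isinstance(similarity, pd.DataFrame) else (
        np.asarray(similarity, dtype=float))
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("similarity matrix must be symmetric")
    z = hierarchy.linkage(pdist(m, metric="euclidean"), method="average")
    labels = None
    if cut_height is not None:
        labels = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    return z, labels


def dendrogram_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy merge table as a Newick string."""
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"
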