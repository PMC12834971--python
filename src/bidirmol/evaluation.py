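"""Evaluation battery: uniqueness/validity/novelty, distribution tests,
fingerprints, 2-D embedding export and property summaries.

The unique / valid / novel percentages form a chain, each stage computed
among the survivors of the previous one: distinct raw strings among all
sampled, syntactically valid among the distinct, and novel (canonical
structure absent from the training set) among the valid.  Distribution
shifts between constrained and unconstrained molecule sets are tested
non-parametrically (Mann-Whitney for medians, Kolmogorov-Smirnov for
whole distributions, both two-sided, no multiple-testing correction).
Chemical-space maps use 2048-bit Morgan fingerprints (radius 2) embedded
to 2-D with t-SNE at a configurable perplexity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .codecs import Scheme, canonical_smiles
from .rewards import qed_term, sa_score

__all__ = [
    "GenerationMetrics",
    "DistributionTestResult",
    "compute_uvn",
    "mw_test",
    "ks_test",
    "distribution_test",
    "morgan_fingerprints",
    "embed_2d",
    "qed_sa_summary",
    "write_metrics_csv",
    "write_test_csv",
    "write_embedding_csv",
]


@dataclass(frozen=True)
class GenerationMetrics:
    pct_unique: float
    pct_valid: float
    pct_novel: float
    n_sampled: int
    n_unique: int = 0
    n_valid: int = 0
    n_novel: int = 0


def compute_uvn(generated: list[str], training_set: set[str] | None,
                scheme: Scheme) -> GenerationMetrics:
    """Chained percentages: unique of sampled, valid of unique, novel of
    valid.  ``training_set`` holds canonical SMILES; novelty is judged at
    the canonical-structure level."""
    if not generated:
        raise ValueError("no generated strings")
    n = len(generated)
    unique = list(dict.fromkeys(generated))
    canon = [canonical_smiles(s, scheme) for s in unique]
    valid = [c for c in canon if c is not None]
    if training_set is None:
        novel = valid
    else:
        novel = [c for c in valid if c not in training_set]
    return GenerationMetrics(
        pct_unique=100.0 * len(unique) / n,
        pct_valid=100.0 * len(valid) / len(unique) if unique else 0.0,
        pct_novel=100.0 * len(novel) / len(valid) if valid else 0.0,
        n_sampled=n, n_unique=len(unique), n_valid=len(valid),
        n_novel=len(novel))


def _degenerate(a, b) -> bool:
    joined = np.concatenate([a, b])
    return np.ptp(joined) == 0


def mw_test(a, b) -> float:
    """Two-sided Mann-Whitney U p-value (identical constants give p=1)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    if _degenerate(a, b):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def ks_test(a, b) -> float:
    """Two-sided two-sample Kolmogorov-Smirnov p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    if _degenerate(a, b):
        return 1.0
    return float(stats.ks_2samp(a, b).pvalue)


@dataclass(frozen=True)
class DistributionTestResult:
    median_constrained: float
    median_null: float
    constrained_higher: bool
    mw_pvalue: float
    ks_pvalue: float


def distribution_test(constrained, null) -> DistributionTestResult:
    constrained = np.asarray(constrained, float)
    null = np.asarray(null, float)
    med_c, med_n = float(np.median(constrained)), float(np.median(null))
    return DistributionTestResult(
        median_constrained=med_c, median_null=med_n,
        constrained_higher=med_c > med_n,
        mw_pvalue=mw_test(constrained, null),
        ks_pvalue=ks_test(constrained, null))


def morgan_fingerprints(mols, radius: int = 2, n_bits: int = 2048
                        ) -> np.ndarray:
    """(n, n_bits) binary matrix of Morgan fingerprints."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits)
    rows = []
    for mol in mols:
        if mol is None:
            raise ValueError("invalid molecule in fingerprint input")
        fp = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
    return np.stack(rows) if rows else np.zeros((0, n_bits), dtype=np.uint8)


def embed_2d(fps: np.ndarray, perplexity: float = 30.0,
             random_state: int = 0) -> np.ndarray:
    """t-SNE embedding of a fingerprint matrix onto the plane."""
    from sklearn.manifold import TSNE

    fps = np.asarray(fps, dtype=np.float64)
    if fps.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {int(3 * perplexity)} points for "
            f"perplexity {perplexity}")
    tsne = TSNE(n_components=2, perplexity=perplexity,
                random_state=random_state, init="pca")
    return tsne.fit_transform(fps)


def qed_sa_summary(mols) -> dict:
    """Mean, std (ddof 1) and median of QED and raw SA scores."""
    qed = np.array([qed_term(m) for m in mols])
    sa = np.array([sa_score(m) for m in mols])
    if qed.size == 0:
        raise ValueError("no molecules")

    def block(x):
        return {
            "mean": float(x.mean()),
            "std": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
        }

    return {"qed": block(qed), "sa": block(sa), "n": int(qed.size)}


def frechet_distance_adapter(fcd_callable, generated_smiles,
                             reference_smiles) -> float:
    """Hook for an externally supplied Fréchet ChemNet Distance.

    The distance needs a pretrained bioactivity network, which this
    package does not ship; pass a callable
    ``f(generated: list[str], reference: list[str]) -> float`` from
    whichever implementation is available and this simply applies it.
    """
    return float(fcd_callable(list(generated_smiles),
                              list(reference_smiles)))


def write_metrics_csv(path, rows: list[dict]) -> None:
    """Rows like {encoding, model, starting_point, n_hidden,
    pct_unique, pct_valid, pct_novel}."""
    fields = ["encoding", "model", "starting_point", "n_hidden",
              "pct_unique", "pct_valid", "pct_novel"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)


def write_test_csv(path, rows: list[dict]) -> None:
    """Rows like {seed, encoding, model, constrained_median, null_median,
    constrained_higher, mw_pvalue, ks_pvalue}."""
    fields = ["seed", "encoding", "model", "constrained_median",
              "null_median", "constrained_higher", "mw_pvalue", "ks_pvalue"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)


def write_embedding_csv(path, coords: np.ndarray, labels: list[dict]) -> None:
    """Coordinates with {model, seed_fragment} labels for plotting."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "model", "seed_fragment"])
        for (x, y), lab in zip(coords, labels):
            writer.writerow([x, y, lab.get("model", ""),
                             lab.get("seed_fragment", "")])
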