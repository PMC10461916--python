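"""Epistasis statistics, significance testing and structural summaries.

Epistasis of a DHFR mutation to a TYMS background follows the additive
model eps = rate(DHFRmut, TYMSmut) - rate(DHFRmut, TYMS WT), valid because
the TYMS variants alone are growth-neutral under thymidine supplementation.
Significance combines a per-mutant Welch (unequal-variance) t-test across
replicates with the Sequential Goodness of Fit (SGoF) family-level
adjustment.  Positions are grouped by their epistasis profile with k-means,
and summarized structurally (distance to the active-site folate C6 atom)
and evolutionarily (alignment-column Kullback-Leibler conservation, Fisher
enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = [
    "compute_epistasis",
    "welch_test",
    "sgof_threshold",
    "SGoFResult",
    "cluster_positions",
    "CLUSTER_LABELS",
    "active_site_distance",
    "active_site_distances",
    "cluster_distance_cdf",
    "column_conservation",
    "alignment_conservation",
    "conservation_enrichment",
]

CLUSTER_LABELS = ("negative", "insignificant", "positive", "strong positive")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided unequal-variance t-test (Welch-Satterthwaite df).

    Returns (t, p).  Convention: zero variance on both sides with equal
    means gives t = 0, p = 1; with unequal means p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test needs >= 2 replicates per side")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compute_epistasis(
    records_bg: pd.DataFrame,
    records_wt: pd.DataFrame,
    background: str | None = None,
) -> pd.DataFrame:
    """Per-mutant epistasis between a TYMS background and the WT background.

    Both inputs are growth-record tables (``infer_growth_rates`` output)
    sharing the ``mutant`` column and carrying per-replicate rates.
    Mutants Null in either background are excluded (epsilon undefined).
    Returns mutant, position, aa, eps, pvalue, background.
    """
    merged = records_bg.merge(
        records_wt, on="mutant", suffixes=("_bg", "_wt"), how="inner"
    )
    rows = []
    for row in merged.itertuples(index=False):
        if row.null_flag_bg or row.null_flag_wt:
            continue
        eps = row.rel_growth_bg - row.rel_growth_wt
        reps_bg = [r for r in row.replicate_rates_bg if r is not None]
        reps_wt = [r for r in row.replicate_rates_wt if r is not None]
        if len(reps_bg) >= 2 and len(reps_wt) >= 2:
            _, p = welch_test(reps_bg, reps_wt)
        else:
            p = np.nan
        rows.append(
            {
                "mutant": row.mutant,
                "position": row.position_bg,
                "aa": row.aa_bg,
                "eps": eps,
                "pvalue": p,
                "background": background,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SGoFResult:
    """Outcome of the SGoF metatest on a family of p-values."""

    n_significant: int
    threshold: float  # largest declared-significant p (nan if none)
    significant: np.ndarray  # boolean mask aligned to the input order
    alpha: float


def sgof_threshold(p_values: Sequence[float], alpha: float = 0.05) -> SGoFResult:
    """Sequential Goodness of Fit multiple-testing adjustment.

    Counts R = #{p <= alpha} and, while that count shows a significant
    excess over its Binomial(n, alpha) expectation (one-sided binomial
    test at level alpha), declares the smallest remaining p-value
    significant, removes it from the family, and repeats on the reduced
    family.  Returns the discovery count, the adjusted threshold (largest
    declared-significant p) and a per-test mask; the discovery set is
    always a prefix of the p-value ranking.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    r = int(np.sum(p <= alpha))
    n_sig = 0
    while (
        r - n_sig > 0
        and stats.binom.sf(r - n_sig - 1, n - n_sig, alpha) <= alpha
    ):
        n_sig += 1
    order = np.argsort(p, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_sig]] = True
    threshold = float(p[order[n_sig - 1]]) if n_sig else float("nan")
    return SGoFResult(
        n_significant=n_sig, threshold=threshold, significant=mask, alpha=alpha
    )


def _position_features(eps_table: pd.DataFrame) -> pd.DataFrame:
    """Per (position, background) feature vector for clustering.

    Features: mean epsilon, mean signed -log10 p (sign of epsilon),
    fraction of mutants with significant epistasis.
    """
    if "significant" not in eps_table.columns:
        raise ValueError("eps_table needs a 'significant' column (run SGoF first)")
    t = eps_table.copy()
    p = np.clip(t["pvalue"].to_numpy(float), 1e-300, 1.0)
    t["signed_logp"] = np.sign(t["eps"]) * (-np.log10(p))
    feats = (
        t.groupby(["position", "background"])
        .agg(
            mean_eps=("eps", "mean"),
            mean_signed_logp=("signed_logp", "mean"),
            frac_significant=("significant", "mean"),
            n_mutants=("eps", "size"),
        )
        .reset_index()
    )
    return feats


def cluster_positions(
    eps_table: pd.DataFrame, k: int = 4, seed: int | None = 0
) -> pd.DataFrame:
    """Sort positions into epistasis categories by k-means (k=4).

    Rows of ``eps_table`` are per-mutant epistasis records (position,
    background, eps, pvalue, significant).  Position-background profiles
    (mean eps, mean signed -log10 p, fraction significant) are
    standardized and clustered; clusters are labeled by centroid mean-eps
    ordering: negative < insignificant < positive < strong positive.
    """
    feats = _position_features(eps_table)
    X = feats[["mean_eps", "mean_signed_logp", "frac_significant"]].to_numpy(float)
    if len(feats) < k:
        raise ValueError(f"k={k} exceeds the {len(feats)} position profiles")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("degenerate clustering: fewer distinct profiles than k")
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Xs)
    centroid_eps = [
        feats.loc[km.labels_ == c, "mean_eps"].mean() for c in range(k)
    ]
    order = np.argsort(centroid_eps)
    label_of = {int(order[i]): CLUSTER_LABELS[i] for i in range(k)}
    feats["cluster"] = [label_of[int(c)] for c in km.labels_]
    return feats


# ---------------------------------------------------------------------------
# structural summaries


def _load_structure(pdb_path):
    from Bio.PDB import PDBParser

    return PDBParser(QUIET=True).get_structure("model", pdb_path)


def _ligand_atom_coord(
    structure, ligand_resname: str, ligand_atom: str
) -> np.ndarray:
    for atom in structure.get_atoms():
        res = atom.get_parent()
        if res.get_resname().strip() == ligand_resname and atom.get_name() == ligand_atom:
            return np.asarray(atom.get_coord(), dtype=float)
    raise ValueError(
        f"ligand atom {ligand_atom} of residue {ligand_resname} not found"
    )


def active_site_distance(
    pdb_path,
    position: int,
    chain: str = "A",
    ligand_resname: str = "FOL",
    ligand_atom: str = "C6",
) -> float:
    """Minimum heavy-atom distance (Angstrom) from a residue to the
    active site, defined as the named atom of the folate ligand."""
    return active_site_distances(
        pdb_path, [position], chain, ligand_resname, ligand_atom
    )[position]


def active_site_distances(
    pdb_path,
    positions: Iterable[int] | None = None,
    chain: str = "A",
    ligand_resname: str = "FOL",
    ligand_atom: str = "C6",
) -> dict[int, float]:
    """Active-site distances for many residues in one structure pass."""
    structure = _load_structure(pdb_path)
    target = _ligand_atom_coord(structure, ligand_resname, ligand_atom)
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not in structure")
    wanted = None if positions is None else set(positions)
    out: dict[int, float] = {}
    for residue in model[chain]:
        het, resseq, _ = residue.get_id()
        if het.strip():
            continue
        if wanted is not None and resseq not in wanted:
            continue
        coords = np.array(
            [a.get_coord() for a in residue if a.element != "H"], dtype=float
        )
        if coords.size == 0:
            continue
        out[resseq] = float(np.min(np.linalg.norm(coords - target, axis=1)))
    if wanted is not None:
        missing = wanted - out.keys()
        if missing:
            raise ValueError(f"residues {sorted(missing)} not found in chain {chain}")
    return out


def cluster_distance_cdf(
    clusters: pd.DataFrame, distances: Mapping[int, float]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Empirical CDF of active-site distance per epistasis cluster.

    ``clusters`` carries position and cluster columns; every clustered
    position must have a distance.  Returns cluster -> (sorted distances,
    cumulative fraction).
    """
    out = {}
    for label, grp in clusters.groupby("cluster"):
        missing = [p for p in grp["position"] if p not in distances]
        if missing:
            raise ValueError(f"no distance for positions {missing}")
        d = np.sort([distances[p] for p in grp["position"]])
        out[label] = (d, np.arange(1, d.size + 1) / d.size)
    return out


# ---------------------------------------------------------------------------
# conservation


def column_conservation(
    column: Sequence[str], background: Mapping[str, float] | None = None
) -> float:
    """Kullback-Leibler relative entropy (nats) of an alignment column.

    Gaps are excluded from the column frequencies; the background must be
    strictly positive over the 20 amino acids (default uniform).  An
    all-gap column is undefined and returns NaN.
    """
    if background is None:
        background = {a: 1.0 / 20.0 for a in AMINO_ACIDS}
    if any(q <= 0 for q in background.values()):
        raise ValueError("background frequencies must be strictly positive")
    residues = [c.upper() for c in column if c.upper() in background]
    if not residues:
        return float("nan")
    vals, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    q = np.array([background[a] for a in vals])
    return float(np.sum(p * np.log(p / q)))


def alignment_conservation(
    sequences: Sequence[str], background: Mapping[str, float] | None = None
) -> np.ndarray:
    """Per-column KL conservation over an equal-length alignment."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal lengths")
    ncol = lengths.pop()
    return np.array(
        [
            column_conservation([s[i] for s in sequences], background)
            for i in range(ncol)
        ]
    )


def conservation_enrichment(
    set_a: Iterable[int], set_b: Iterable[int], total_positions: int
) -> tuple[float, float]:
    """Fisher exact association between two position sets.

    Builds the 2x2 membership table over ``total_positions`` and returns
    (odds ratio, two-sided exact p).  Degenerate margins (either set empty
    or full) give p = 1 by convention.
    """
    a, b = set(set_a), set(set_b)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = total_positions - n11 - n10 - n01
    if n00 < 0:
        raise ValueError("sets exceed total_positions")
    table = np.array([[n11, n10], [n01, n00]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
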