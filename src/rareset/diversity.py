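"""Distance, clustering, sensitivity and spatial analyses.

Euclidean distances between binary bulk profiles (or accession z-profiles)
feed a UPGMA dendrogram; bulk-pair distances split into within- vs
between-accession populations, compared by a Welch t-test, quantify how
solid the grouping of plants into accessions is; a leave-one-column-out
jackknife scores each marker/allele combination's influence on the tree;
and a Mantel test relates genetic distance to great-circle geographic
distance between collection sites.

Caveat on the t-test: pair distances are not independent observations, so
the p-value is anti-conservative; a permutation alternative is available
via ``permutations > 0``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import mantel

from .marker_matrix import BULK_ID_SEP, AccessionMatrix, BulkMatrix, Matrix

EARTH_RADIUS_KM = 6371.0


def pairwise_distances(m: Matrix) -> DistanceMatrix:
    """Euclidean distances between entity profiles.

    Bulk matrices yield one entity per bulk (ids ``"accession·bulk"``,
    binary profiles); accession matrices one entity per accession
    (z profiles in 0..B).
    """
    if isinstance(m, BulkMatrix):
        ids = [f"{a}{BULK_ID_SEP}{b}" for a, b in m.data.index]
    else:
        ids = [str(a) for a in m.data.index]
    if len(ids) < 2:
        raise ValueError("pairwise distances need at least 2 entities")
    d = squareform(pdist(m.data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=ids)


@dataclass
class WBStats:
    """Within- vs between-accession bulk distance comparison."""

    mean_within: float
    mean_between: float
    median_within: float
    median_between: float
    ratio_between_over_within: float
    t_statistic: float
    p_value: float
    n_within_pairs: int
    n_between_pairs: int
    mean_all: float
    median_all: float
    min_all: float
    max_all: float
    note: str = ""


def bulk_groups_from_ids(ids) -> pd.Series:
    """Recover the accession of each ``"accession·bulk"`` entity id."""
    return pd.Series(
        {i: i.rsplit(BULK_ID_SEP, 1)[0] for i in ids}, name="accession"
    )


def within_between_stats(
    d: DistanceMatrix,
    groups: pd.Series | None = None,
    permutations: int = 0,
    seed: int | None = None,
) -> WBStats:
    """Split bulk-pair distances into within/between populations and test them.

    ``groups`` maps each entity id to its accession; by default it is parsed
    from ``"accession·bulk"`` ids. The test is a Welch two-sample t-test of
    between-pairs vs within-pairs; with ``permutations > 0`` the p-value is
    replaced by a permutation p-value of the same statistic.
    """
    ids = list(d.ids)
    if groups is None:
        groups = bulk_groups_from_ids(ids)
    g = groups.reindex(pd.Index(ids))
    if g.isna().any():
        raise ValueError(f"no accession for entities: {list(g.index[g.isna()])}")
    labels = g.to_numpy()
    mat = d.data
    iu = np.triu_indices(len(ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    within = mat[iu][same]
    between = mat[iu][~same]
    if within.size == 0:
        raise ValueError("no within-accession pairs (each accession has one bulk)")
    if between.size == 0:
        raise ValueError("no between-accession pairs (single accession)")

    note = ""
    if np.ptp(within) == 0 and np.ptp(between) == 0 and within[0] == between[0]:
        t_stat, p = float("nan"), float("nan")
        note = "all pair distances identical; t-test undefined"
    elif permutations > 0:
        def welch_t(x, y, axis=-1):
            return stats.ttest_ind(x, y, equal_var=False, axis=axis).statistic

        res = stats.permutation_test(
            (between, within),
            welch_t,
            permutation_type="independent",
            n_resamples=permutations,
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        t_stat, p = float(res.statistic), float(res.pvalue)
        note = f"permutation p-value ({permutations} permutations)"
    else:
        res = stats.ttest_ind(between, within, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)

    all_d = mat[iu]
    mw, mb = float(within.mean()), float(between.mean())
    return WBStats(
        mean_within=mw,
        mean_between=mb,
        median_within=float(np.median(within)),
        median_between=float(np.median(between)),
        ratio_between_over_within=mb / mw if mw else float("nan"),
        t_statistic=t_stat,
        p_value=p,
        n_within_pairs=int(within.size),
        n_between_pairs=int(between.size),
        mean_all=float(all_d.mean()),
        median_all=float(np.median(all_d)),
        min_all=float(all_d.min()),
        max_all=float(all_d.max()),
        note=note,
    )


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering into a rooted ultrametric tree.

    Tie-break among minimal-distance pairs: merge the pair whose sorted
    member-label tuples compare lexicographically smallest, so the result
    is reproducible regardless of input order. Children of each node are
    emitted in lexicographic order in the Newick serialization; branch
    lengths place every leaf at (merge height)/2 from each internal node.
    """
    labels = [str(x) for x in d.ids]
    mat = np.asarray(d.data, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")

    # cluster state: members (sorted label tuple), size, height, newick
    clusters: dict[int, dict] = {
        i: {"members": (lab,), "size": 1, "height": 0.0, "newick": lab}
        for i, lab in enumerate(labels)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): mat[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    while len(clusters) > 1:
        # minimal distance, then lexicographically smallest member-tuple pair
        def pair_key(key: frozenset[int]):
            a, b = sorted(key, key=lambda c: clusters[c]["members"])
            return (dist[key], clusters[a]["members"], clusters[b]["members"])

        best = min(dist, key=pair_key)
        a, b = sorted(best, key=lambda c: clusters[c]["members"])
        h = float(dist[best]) / 2.0
        ca, cb = clusters.pop(a), clusters.pop(b)
        dist.pop(best)
        children = sorted((ca, cb), key=lambda c: c["members"])
        parts = ",".join(
            f"{c['newick']}:{float(h - c['height'])!r}" for c in children
        )
        new = {
            "members": tuple(sorted(ca["members"] + cb["members"])),
            "size": ca["size"] + cb["size"],
            "height": h,
            "newick": f"({parts})",
        }
        # proportional (size-weighted) average linkage to every other cluster
        for other in list(clusters):
            ka, kb = frozenset((a, other)), frozenset((b, other))
            dnew = (ca["size"] * dist.pop(ka) + cb["size"] * dist.pop(kb)) / new[
                "size"
            ]
            dist[frozenset((next_id, other))] = dnew
        clusters[next_id] = new
        next_id += 1

    root = next(iter(clusters.values()))
    return TreeNode.read(io.StringIO(root["newick"] + ";"))


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (equals merge height for UPGMA trees)."""
    return tree.tip_tip_distances()


def jackknife_columns(m: AccessionMatrix) -> pd.DataFrame:
    """Column-exclusion sensitivity of the accession-level UPGMA dendrogram.

    For each column j the distances and tree are rebuilt without j;
    sensitivity_j = 1 - Pearson correlation between the cophenetic
    distance vectors of the full and reduced trees. Constant or duplicated
    columns have sensitivity 0.
    """
    if len(m.columns) < 2:
        raise ValueError("jackknife needs at least 2 columns")
    full_tree = upgma(pairwise_distances(m))
    ids = sorted(str(a) for a in m.data.index)
    full_coph = cophenetic_matrix(full_tree).filter(ids).condensed_form()
    rows = []
    for col in m.columns:
        reduced = AccessionMatrix(
            data=m.data.drop(columns=[col]),
            bulks_per_accession=m.bulks_per_accession,
        )
        coph = cophenetic_matrix(upgma(pairwise_distances(reduced)))
        vec = coph.filter(ids).condensed_form()
        if np.ptp(vec) == 0 or np.ptp(full_coph) == 0:
            sens = 0.0 if np.allclose(vec, full_coph) else float("nan")
        else:
            sens = 1.0 - float(stats.pearsonr(full_coph, vec).statistic)
        rows.append({"column": col, "sensitivity": sens})
    return pd.DataFrame(rows)


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distances(meta: pd.DataFrame, ids: list[str]) -> DistanceMatrix:
    sub = meta.reindex(pd.Index(ids))
    missing = [i for i in ids if i not in meta.index or sub.loc[i, ["lat", "lon"]].isna().any()]
    if missing:
        raise ValueError(f"missing coordinates for accession(s): {missing}")
    lat = sub["lat"].to_numpy(dtype=float)
    lon = sub["lon"].to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i + 1 :] = haversine_km(lat[i], lon[i], lat[i + 1 :], lon[i + 1 :])
    out = out + out.T
    return DistanceMatrix(out, ids=ids)


def geo_genetic_correlation(
    meta: pd.DataFrame,
    d: DistanceMatrix,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Pearson correlation between geographic and genetic distances.

    Returns ``{"r", "mantel_p", "n"}``; with ``permutations == 0`` only the
    plain Pearson r on the condensed vectors is computed and ``mantel_p``
    is None. When geographic distances are all zero the correlation is
    undefined and reported as NaN.
    """
    ids = list(d.ids)
    geo = geographic_distances(meta, ids)
    gvec = geo.condensed_form()
    dvec = d.condensed_form()
    if np.ptp(gvec) == 0 or np.ptp(dvec) == 0:
        return {"r": float("nan"), "mantel_p": None, "n": len(ids)}
    if permutations > 0:
        r, p, n = mantel(geo, d, method="pearson", permutations=permutations, seed=seed)
        return {"r": float(r), "mantel_p": float(p), "n": int(n)}
    r = float(stats.pearsonr(gvec, dvec).statistic)
    return {"r": r, "mantel_p": None, "n": len(ids)}
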