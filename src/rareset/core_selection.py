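"""Core-collection selection: the AMA greedy cover and an exact oracle.

AMA ("All Marker Alleles") selects a small accession subset covering every
marker/allele combination present in the collection. It is a greedy set
cover with rarity prioritisation, fully deterministic:

1. seed with the accession of highest rareness R_i
   (ties: lexicographically smallest accession id);
2. repeatedly add the accession giving the largest gain in newly covered
   columns (ties: higher R_i, then lexicographically smallest id);
3. stop when every coverable column is covered.

Greedy set cover does not guarantee a minimum set but is close to it; the
classical bound |greedy| <= (1 + ln M) * |optimum| applies. An exhaustive
minimum-cover search (N <= 20) is provided as the optimality oracle, along
with quality metrics for comparing any externally produced core set.

A column is "present in" an accession when its z-score is >= 1 — a single
bulk suffices to witness an allele in pooled genotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .marker_matrix import AccessionMatrix

BRUTE_FORCE_MAX_N = 20


@dataclass
class CoreSet:
    """Selected core with per-step bookkeeping and quality summary."""

    selected: list[str]
    step_log: pd.DataFrame  # step, accession, gain, R, cumulative_coverage
    covered_columns: set[str]
    coverage: float
    mean_R: float | None
    uncoverable_columns: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.selected)


def _presence(a: AccessionMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    p = a.data.to_numpy() >= 1
    return p, list(a.data.index.astype(str)), list(a.data.columns)


def _split_coverable(p: np.ndarray, columns: list[str]):
    coverable = p.any(axis=0)
    uncoverable = tuple(c for c, ok in zip(columns, coverable) if not ok)
    if uncoverable:
        warnings.warn(
            f"{len(uncoverable)} column(s) present in no accession are excluded "
            f"from the coverage target: {list(uncoverable)[:5]}...",
            stacklevel=3,
        )
    return coverable, uncoverable


def ama_select(a: AccessionMatrix, r: pd.Series) -> CoreSet:
    """Run the AMA greedy cover; ``r`` holds R_i aligned with ``a``."""
    p, ids, columns = _presence(a)
    if set(r.index.astype(str)) != set(ids) or len(r) != len(ids):
        raise ValueError("rareness values are not aligned with the matrix accessions")
    rvals = r.reindex(a.data.index).to_numpy(dtype=float)
    coverable, uncoverable = _split_coverable(p, columns)
    n_target = int(coverable.sum())

    selected_idx: list[int] = []
    log_rows = []
    covered = np.zeros(len(columns), dtype=bool)
    remaining = set(range(len(ids)))

    def pick(order_key):
        best = min(remaining, key=order_key)
        return best

    # seed: highest R, ties to lexicographically smallest id
    seed = pick(lambda i: (-rvals[i], ids[i]))
    while True:
        if not selected_idx:
            choice = seed
        else:
            gains = {i: int((p[i] & coverable & ~covered).sum()) for i in remaining}
            best_gain = max(gains.values(), default=0)
            if best_gain == 0:
                break
            choice = pick(lambda i: (-gains[i], -rvals[i], ids[i]))
        gain = int((p[choice] & coverable & ~covered).sum())
        covered |= p[choice] & coverable
        selected_idx.append(choice)
        remaining.discard(choice)
        log_rows.append(
            {
                "step": len(selected_idx),
                "accession": ids[choice],
                "gain": gain,
                "R": rvals[choice],
                "cumulative_coverage": covered.sum() / n_target if n_target else 1.0,
            }
        )
        if covered.sum() >= n_target or not remaining:
            break

    selected = [ids[i] for i in selected_idx]
    covered_cols = {c for c, ok in zip(columns, covered) if ok}
    return CoreSet(
        selected=selected,
        step_log=pd.DataFrame(log_rows),
        covered_columns=covered_cols,
        coverage=len(covered_cols) / n_target if n_target else 1.0,
        mean_R=float(np.mean([rvals[i] for i in selected_idx])) if selected_idx else None,
        uncoverable_columns=uncoverable,
    )


def brute_force_min_cover(
    a: AccessionMatrix, r: pd.Series | None = None
) -> CoreSet:
    """Exhaustive minimum-cardinality cover (optimality oracle, N <= 20).

    Subsets are enumerated by size then lexicographic id order, so among
    minimum covers the lexicographically smallest id tuple is returned.
    """
    p, ids, columns = _presence(a)
    n = len(ids)
    if n > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"brute-force search is limited to N <= {BRUTE_FORCE_MAX_N} accessions "
            f"(got {n}); use ama_select for larger collections"
        )
    coverable, uncoverable = _split_coverable(p, columns)
    n_target = int(coverable.sum())
    order = sorted(range(n), key=lambda i: ids[i])
    rvals = (
        r.reindex(a.data.index).to_numpy(dtype=float) if r is not None else None
    )

    best: tuple[int, ...] | None = None
    if n_target == 0:
        best = ()
    else:
        for size in range(1, n + 1):
            for combo in combinations(order, size):
                if (p[list(combo)].any(axis=0) & coverable).sum() == n_target:
                    best = combo
                    break
            if best is not None:
                break
    assert best is not None

    covered = np.zeros(len(columns), dtype=bool)
    log_rows = []
    for step, i in enumerate(best, start=1):
        gain = int((p[i] & coverable & ~covered).sum())
        covered |= p[i] & coverable
        log_rows.append(
            {
                "step": step,
                "accession": ids[i],
                "gain": gain,
                "R": float(rvals[i]) if rvals is not None else np.nan,
                "cumulative_coverage": covered.sum() / n_target if n_target else 1.0,
            }
        )
    covered_cols = {c for c, ok in zip(columns, covered) if ok}
    mean_R = (
        float(np.mean([rvals[i] for i in best])) if rvals is not None and best else None
    )
    return CoreSet(
        selected=[ids[i] for i in best],
        step_log=pd.DataFrame(
            log_rows,
            columns=["step", "accession", "gain", "R", "cumulative_coverage"],
        ),
        covered_columns=covered_cols,
        coverage=len(covered_cols) / n_target if n_target else 1.0,
        mean_R=mean_R,
        uncoverable_columns=uncoverable,
    )


def core_metrics(c: CoreSet, a: AccessionMatrix, r: pd.Series) -> dict:
    """Quality metrics of a core set against its source matrix.

    Returns size, coverage (fraction of coverable columns covered),
    mean rareness of the selected accessions, and per-column redundancy
    (how many selected accessions present each column).
    """
    p, ids, columns = _presence(a)
    unknown = [x for x in c.selected if x not in set(ids)]
    if unknown:
        raise ValueError(f"core set contains unknown accession(s): {unknown}")
    coverable = p.any(axis=0)
    sel_rows = [ids.index(x) for x in c.selected]
    if sel_rows:
        sel_p = p[sel_rows]
        covered = sel_p.any(axis=0) & coverable
        redundancy = pd.Series(sel_p.sum(axis=0), index=columns, name="redundancy")
        mean_R = float(r.reindex(pd.Index(c.selected)).mean())
    else:
        covered = np.zeros(len(columns), dtype=bool)
        redundancy = pd.Series(0, index=columns, name="redundancy")
        mean_R = None
    n_target = int(coverable.sum())
    return {
        "size": len(c.selected),
        "coverage": covered.sum() / n_target if n_target else 1.0,
        "mean_R": mean_R,
        "redundancy": redundancy,
    }
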