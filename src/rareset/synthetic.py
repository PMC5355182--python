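"""Seeded simulator of bulked SSR genotyping of a landrace collection.

The generative model mirrors the bulk design of the study system: a
collection of accessions (default 185) genotyped at several SSR loci
(default 14) as B bulks (default 3) of n plants (default 10) per accession.
Each diploid plant contributes ``ploidy`` haplotypes, so one bulk draws
``n * ploidy`` haplotypes per marker from the accession's allele-frequency
vector; an allele is scored present in the bulk when drawn at least once —
hence the closed-form per-bulk detection probability
``1 - (1 - p)^(n * ploidy)``.

Structure comes from a three-level Dirichlet hierarchy (collection-wide
base frequencies -> race frequencies -> accession frequencies), optional
altitude tilts of selected alleles (logistic on the frequency scale),
planted rare/private alleles with known carriers, race-clustered collection
coordinates, and an optional per-bulk false-negative rate emulating missed
PCR calls. Everything is reproducible from the seed.

No linkage, mutation model or fragment-size realism is attempted: markers
are treated as independent loci, as appropriate for a panel spread over
all chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .marker_matrix import (
    AccessionMatrix,
    BulkMatrix,
    make_label,
)

#: Per-marker allele counts shaping the default panel: 14 SSR loci whose
#: combined allele universe has 278 marker/allele combinations.
DEFAULT_ALLELE_COUNTS_14 = (20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 19, 19)

KERNEL_COLORS = ("white", "yellow", "blue", "red", "mixed")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated collection.

    ``race_frequency_divergence`` controls how far race allele-frequency
    vectors drift from the collection base (0 = none; larger = more);
    ``accession_concentration`` is the Dirichlet concentration tying
    accessions to their race frequencies (larger = tighter).
    ``planted_rare`` entries are (accession_id, marker, allele_label,
    within-accession frequency) and introduce a private allele carried only
    by that accession. ``masl_effects`` entries are (column_label, slope):
    the allele's frequency weight is multiplied by
    ``exp(slope * (masl - 1900) / 1000)`` and the marker renormalized.
    """

    n_accessions: int = 185
    n_markers: int = 14
    alleles_per_marker: int | Sequence[int] | None = None
    n_races: int = 16
    race_frequency_divergence: float = 0.5
    bulks_per_accession: int = 3
    plants_per_bulk: int = 10
    ploidy: int = 2
    accession_concentration: float = 20.0
    planted_rare: tuple[tuple[str, str, str, float], ...] = ()
    masl_effects: tuple[tuple[str, float], ...] = ()
    false_negative_rate: float = 0.0
    masl_range: tuple[float, float] = (800.0, 3000.0)
    lat_range: tuple[float, float] = (17.8, 20.2)
    lon_range: tuple[float, float] = (-98.9, -96.6)
    geo_cluster_sd: float = 0.15
    seed: int = 0

    def allele_counts(self) -> tuple[int, ...]:
        apm = self.alleles_per_marker
        if apm is None:
            base = DEFAULT_ALLELE_COUNTS_14
            return tuple(base[i % len(base)] for i in range(self.n_markers))
        if isinstance(apm, int):
            return (apm,) * self.n_markers
        counts = tuple(int(x) for x in apm)
        if len(counts) != self.n_markers:
            raise ValueError("alleles_per_marker length must equal n_markers")
        return counts


@dataclass
class SimTruth:
    """Ground truth of a simulated collection, for recovery tests."""

    frequencies: pd.DataFrame  # accession, marker, allele, freq (long)
    races: pd.Series  # accession -> race label
    masl: pd.Series
    coordinates: pd.DataFrame  # accession -> lat, lon
    planted_rare: tuple[tuple[str, str, str, float], ...]
    config: SimConfig


def detection_probability(
    p: float | np.ndarray, plants_per_bulk: int, ploidy: int = 2
) -> float | np.ndarray:
    """Probability a bulk of ``plants_per_bulk`` plants reveals an allele.

    With within-accession allele frequency ``p`` and ``n * ploidy``
    independently drawn haplotypes per bulk, detection requires at least one
    carrying haplotype: ``1 - (1 - p)^(n * ploidy)``.
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("allele frequency must be in [0, 1]")
    if plants_per_bulk < 1:
        raise ValueError("plants_per_bulk must be >= 1")
    out = 1.0 - (1.0 - arr) ** (plants_per_bulk * ploidy)
    return float(out) if np.isscalar(p) else out


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    return rng.dirichlet(np.clip(alpha, 1e-6, None))


def private_allele_plan(
    accessions: Sequence[str],
    n_markers: int,
    frequency: float = 0.5,
) -> tuple[tuple[str, str, str, float], ...]:
    """Planting plan making each listed accession genuinely rare.

    Each accession receives one private allele per marker at the given
    within-accession frequency — the allele content of a fully distinct
    genotype (an outgroup-like accession), which is what the rareness
    coefficient is meant to flag. Allele labels ``P<acc>`` are unique per
    accession and collide with nothing the simulator generates.
    """
    return tuple(
        (acc, f"SSR{m + 1:02d}", f"P{acc}", float(frequency))
        for acc in accessions
        for m in range(n_markers)
    )


def simulate_collection(
    cfg: SimConfig,
) -> tuple[BulkMatrix, pd.DataFrame, SimTruth]:
    """Generate a bulked-genotyping dataset plus metadata and ground truth.

    The returned BulkMatrix carries one column for every allele of the
    configured universe (including planted private alleles), sorted by
    (marker, allele); alleles that happen never to be drawn appear as
    all-zero columns.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.allele_counts()
    markers = [f"SSR{i + 1:02d}" for i in range(cfg.n_markers)]
    alleles: dict[str, list[str]] = {
        m: [str(80 + 3 * k) for k in range(c)] for m, c in zip(markers, counts)
    }
    accessions = [f"ACC{i + 1:03d}" for i in range(cfg.n_accessions)]
    races = [f"R{i + 1:02d}" for i in range(cfg.n_races)]
    race_of = {a: races[i % cfg.n_races] for i, a in enumerate(accessions)}

    # collection base and race-level frequency vectors
    base = {m: _dirichlet(rng, np.ones(len(alleles[m]))) for m in markers}
    race_freq: dict[str, dict[str, np.ndarray]] = {}
    for r in races:
        race_freq[r] = {}
        for m in markers:
            if cfg.race_frequency_divergence <= 0:
                race_freq[r][m] = base[m].copy()
            else:
                conc = len(alleles[m]) / cfg.race_frequency_divergence
                race_freq[r][m] = _dirichlet(rng, base[m] * conc)

    # race-correlated altitude and geography
    lo, hi = cfg.masl_range
    race_masl = {r: rng.uniform(lo, hi) for r in races}
    masl = pd.Series(
        {
            a: float(
                np.clip(race_masl[race_of[a]] + rng.normal(0, (hi - lo) / 12), lo, hi)
            )
            for a in accessions
        },
        name="masl",
    )
    race_lat = {r: rng.uniform(*cfg.lat_range) for r in races}
    race_lon = {r: rng.uniform(*cfg.lon_range) for r in races}
    coords = pd.DataFrame(
        {
            "lat": [
                float(np.clip(race_lat[race_of[a]] + rng.normal(0, cfg.geo_cluster_sd),
                              *cfg.lat_range))
                for a in accessions
            ],
            "lon": [
                float(np.clip(race_lon[race_of[a]] + rng.normal(0, cfg.geo_cluster_sd),
                              *cfg.lon_range))
                for a in accessions
            ],
        },
        index=pd.Index(accessions, name="accession"),
    )

    # accession-level frequencies around the race vectors
    freq: dict[str, dict[str, np.ndarray]] = {}
    for a in accessions:
        freq[a] = {
            m: _dirichlet(
                rng, race_freq[race_of[a]][m] * cfg.accession_concentration
            )
            for m in markers
        }

    # altitude tilts: multiply the target allele's weight, renormalize
    masl_mid = 1900.0
    for label, slope in cfg.masl_effects:
        m, al = label.rsplit("_", 1)
        if m not in alleles or al not in alleles[m]:
            raise ValueError(f"masl effect targets unknown column {label!r}")
        k = alleles[m].index(al)
        for a in accessions:
            w = freq[a][m].copy()
            w[k] *= np.exp(slope * (masl[a] - masl_mid) / 1000.0)
            freq[a][m] = w / w.sum()

    # planted rare/private alleles
    for acc, m, al, f in cfg.planted_rare:
        if acc not in freq:
            raise ValueError(f"planted rare accession {acc!r} not in collection")
        if m not in alleles:
            raise ValueError(f"planted rare marker {m!r} unknown")
        if al in alleles[m]:
            raise ValueError(
                f"planted allele {al!r} collides with an existing allele of {m}"
            )
        if not 0 < f <= 1:
            raise ValueError("planted allele frequency must be in (0, 1]")
        alleles[m].append(al)
        for a in accessions:
            old = freq[a][m]
            extra = f if a == acc else 0.0
            freq[a][m] = np.append(old * (1.0 - extra), extra)

    columns = sorted(
        (make_label(m, al) for m in markers for al in alleles[m]),
        key=lambda lab: lab.rsplit("_", 1),
    )
    col_index = {lab: j for j, lab in enumerate(columns)}
    haplotypes = cfg.plants_per_bulk * cfg.ploidy

    index = pd.MultiIndex.from_tuples(
        [(a, b) for a in accessions for b in range(1, cfg.bulks_per_accession + 1)],
        names=["accession", "bulk"],
    )
    data = np.zeros((len(index), len(columns)), dtype=np.int64)
    row = 0
    for a in accessions:
        for _b in range(cfg.bulks_per_accession):
            for m in markers:
                draws = rng.multinomial(haplotypes, freq[a][m])
                present = np.nonzero(draws)[0]
                for k in present:
                    data[row, col_index[make_label(m, alleles[m][k])]] = 1
            row += 1
    if cfg.false_negative_rate > 0:
        drop = rng.random(data.shape) < cfg.false_negative_rate
        data[drop & (data == 1)] = 0

    bulk = BulkMatrix(
        data=pd.DataFrame(data, index=index, columns=columns),
        bulks_per_accession=cfg.bulks_per_accession,
    )

    meta = pd.DataFrame(
        {
            "race1": [race_of[a] for a in accessions],
            "race2": [
                race_of[a]
                if rng.random() > 0.3
                else races[int(rng.integers(cfg.n_races))]
                for a in accessions
            ],
            "kernel_color": [
                KERNEL_COLORS[
                    (races.index(race_of[a]) + int(rng.integers(2)))
                    % len(KERNEL_COLORS)
                ]
                for a in accessions
            ],
            "lat": coords["lat"],
            "lon": coords["lon"],
            "masl": masl,
        },
        index=pd.Index(accessions, name="accession"),
    )

    freq_long = pd.DataFrame(
        [
            (a, m, al, float(freq[a][m][k]))
            for a in accessions
            for m in markers
            for k, al in enumerate(alleles[m])
        ],
        columns=["accession", "marker", "allele", "freq"],
    )
    truth = SimTruth(
        frequencies=freq_long,
        races=pd.Series(race_of, name="race1"),
        masl=masl,
        coordinates=coords,
        planted_rare=cfg.planted_rare,
        config=cfg,
    )
    return bulk, meta, truth


@dataclass
class Fixture:
    bulk: BulkMatrix
    accession: AccessionMatrix
    metadata: pd.DataFrame
    truth: SimTruth | None = None


def make_fixture(name: str) -> Fixture:
    """Named deterministic fixtures used across the documentation and tests.

    * ``"F1"`` — the 3-accession, 3-column hand example (B = 1) whose
      rareness values are (1/3, 1/9, 2/9) and whose greedy core is [A, C];
    * ``"F2"`` — a seeded 5-accession x 3-bulk collection at 3 small loci;
    * ``"survey_shape"`` — a seeded 240-accession x 3-bulk collection with
      36 race labels and exactly 278 marker/allele columns (720 bulk rows),
      the shape of a full landrace-survey matrix.
    """
    from .marker_matrix import collapse_bulks

    if name == "F1":
        cols = ["M1_a", "M2_a", "M3_a"]
        index = pd.MultiIndex.from_tuples(
            [("A", 1), ("B", 1), ("C", 1)], names=["accession", "bulk"]
        )
        data = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1], [0, 0, 1]], index=index, columns=cols
        )
        bulk = BulkMatrix(data=data, bulks_per_accession=1)
        meta = pd.DataFrame(
            {
                "race1": ["X", "X", "Y"],
                "race2": [None, None, None],
                "kernel_color": ["white", "white", "blue"],
                "lat": [19.0, 19.1, 19.5],
                "lon": [-98.0, -98.1, -97.5],
                "masl": [2000.0, 2100.0, 2400.0],
            },
            index=pd.Index(["A", "B", "C"], name="accession"),
        )
        return Fixture(bulk=bulk, accession=collapse_bulks(bulk), metadata=meta)
    if name == "F2":
        cfg = SimConfig(
            n_accessions=5,
            n_markers=3,
            alleles_per_marker=4,
            n_races=2,
            seed=20,
        )
        bulk, meta, truth = simulate_collection(cfg)
        return Fixture(
            bulk=bulk, accession=collapse_bulks(bulk), metadata=meta, truth=truth
        )
    if name == "survey_shape":
        cfg = SimConfig(
            n_accessions=240,
            n_markers=14,
            alleles_per_marker=DEFAULT_ALLELE_COUNTS_14,
            n_races=36,
            seed=278,
        )
        bulk, meta, truth = simulate_collection(cfg)
        # guarantee the full 278-column universe is witnessed at least once:
        # pin each never-drawn allele into one bulk, round-robin over rows
        data = bulk.data
        empty = [c for c in data.columns if data[c].sum() == 0]
        for k, col in enumerate(empty):
            data.iloc[k % len(data), data.columns.get_loc(col)] = 1
        return Fixture(
            bulk=bulk, accession=collapse_bulks(bulk), metadata=meta, truth=truth
        )
    raise ValueError(f"unknown fixture {name!r}")
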