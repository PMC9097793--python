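"""Population genetic statistics from aligned cpDNA haplotype data.

A species dataset couples a pool of aligned haplotype sequences with
population samples (haplotype counts at georeferenced sites).  Chloroplast
markers are effectively haploid and uniparentally inherited, so each
individual carries exactly one haplotype and all statistics operate on
haplotype frequencies and pairwise sequence distances.

Statistics implemented:

* haplotype diversity ``H_D`` — Nei's unbiased estimator
  ``n/(n-1) * (1 - sum p_i^2)``;
* nucleotide diversity ``pi`` — expected per-site proportion of differences
  between two randomly drawn sequences, with pairwise deletion of gap/``N``
  positions;
* pairwise ``Phi_ST`` — two-population AMOVA on squared haplotype distances
  (pairwise nucleotide difference counts), the estimator Arlequin applies to
  haplotypic sequence data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats as _sps

__all__ = [
    "Haplotype",
    "PopulationSample",
    "SpeciesDataset",
    "DiversityTable",
    "PairwiseFstMatrix",
    "read_species_dataset",
    "filter_min_sample",
    "haplotype_diversity",
    "nucleotide_diversity",
    "pairwise_phist",
    "fst_matrix",
    "index_correlation",
    "diversity_table",
]

_VALID_BASES = frozenset("ACGT")


class DatasetError(ValueError):
    """Raised when haplotype/population inputs violate the data contract."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested for an input it is undefined on."""


@dataclass(frozen=True)
class Haplotype:
    """One distinct cpDNA sequence variant, aligned within its species."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise DatasetError(f"haplotype {self.id!r} has empty sequence")


@dataclass
class PopulationSample:
    """Haplotype counts sampled at one georeferenced population."""

    pop_id: str
    longitude: float
    latitude: float
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if not -180.0 <= self.longitude <= 180.0:
            raise DatasetError(f"population {self.pop_id!r}: longitude {self.longitude} out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise DatasetError(f"population {self.pop_id!r}: latitude {self.latitude} out of range")
        for hap, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise DatasetError(
                    f"population {self.pop_id!r}: negative or non-integer count {c} for haplotype {hap!r}"
                )
        self.counts = {h: int(c) for h, c in self.counts.items() if c > 0}

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class SpeciesDataset:
    """Haplotype pool plus population samples for one species."""

    species: str
    haplotypes: list[Haplotype]
    populations: list[PopulationSample]
    #: set by :func:`filter_min_sample` when the filter removed every population
    empty_after_filter: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        ids = [h.id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise DatasetError(f"{self.species}: duplicate haplotype ids")
        lengths = {len(h.sequence) for h in self.haplotypes}
        if len(lengths) > 1:
            raise DatasetError(
                f"{self.species}: haplotype sequences have unequal lengths {sorted(lengths)}; "
                "inputs must be pre-aligned"
            )
        pop_ids = [p.pop_id for p in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise DatasetError(f"{self.species}: duplicate population ids")
        pool = {h.id for h in self.haplotypes}
        for p in self.populations:
            missing = sorted(set(p.counts) - pool)
            if missing:
                raise DatasetError(
                    f"{self.species}, population {p.pop_id!r}: haplotype id(s) "
                    f"{', '.join(repr(m) for m in missing)} not present in the FASTA pool"
                )

    @property
    def haplotype_index(self) -> dict[str, int]:
        return {h.id: i for i, h in enumerate(self.haplotypes)}

    def expanded_matrix(self, pop: PopulationSample) -> list[str]:
        """Per-individual sequence matrix: each haplotype repeated `count` times."""
        seq = {h.id: h.sequence for h in self.haplotypes}
        rows: list[str] = []
        for hap_id in sorted(pop.counts):
            rows.extend([seq[hap_id]] * pop.counts[hap_id])
        return rows


#: DiversityTable is a pandas DataFrame with columns
#: species, pop_id, lon, lat, N, H_D, pi — one row per retained population.
DiversityTable = pd.DataFrame


@dataclass
class PairwiseFstMatrix:
    """Symmetric per-species Phi_ST matrix; raw (possibly negative) entries."""

    pop_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pop_ids), len(self.pop_ids)):
            raise DatasetError("Phi_ST matrix shape does not match pop_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DatasetError("Phi_ST matrix is not symmetric")
        self.values = v

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, pi in enumerate(self.pop_ids):
            for j, pj in enumerate(self.pop_ids):
                if i < j:
                    rows.append((pi, pj, self.values[i, j]))
        return pd.DataFrame(rows, columns=["pop_i", "pop_j", "phist"])

    def to_square(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pop_ids, columns=self.pop_ids)


# ---------------------------------------------------------------------------
# I/O

POPULATION_TABLE_COLUMNS = ["species", "pop_id", "lon", "lat", "haplotype", "count"]


def read_species_dataset(fasta_path, population_table, species: str) -> SpeciesDataset:
    """Load one species' aligned haplotype FASTA and its population rows.

    The population table is a CSV with header
    ``species,pop_id,lon,lat,haplotype,count``; rows are aggregated by
    ``pop_id``.  Referential integrity (every haplotype id used by a
    population exists in the FASTA) and alignment (equal sequence lengths)
    are enforced at load time.
    """
    haplotypes = [
        Haplotype(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not haplotypes:
        raise DatasetError(f"no FASTA records in {fasta_path}")

    table = pd.read_csv(population_table)
    missing_cols = [c for c in POPULATION_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise DatasetError(f"population table missing column(s): {missing_cols}")
    table = table[table["species"] == species]
    if table.empty:
        raise DatasetError(f"no population rows for species {species!r}")
    if (table["count"] < 0).any():
        bad = table.loc[table["count"] < 0].iloc[0]
        raise DatasetError(f"negative count for {bad['pop_id']!r}/{bad['haplotype']!r}")

    populations = []
    for pop_id, grp in table.groupby("pop_id", sort=False):
        lon = float(grp["lon"].iloc[0])
        lat = float(grp["lat"].iloc[0])
        counts: dict[str, int] = {}
        for _, row in grp.iterrows():
            counts[str(row["haplotype"])] = counts.get(str(row["haplotype"]), 0) + int(row["count"])
        populations.append(PopulationSample(str(pop_id), lon, lat, counts))
    return SpeciesDataset(species=species, haplotypes=haplotypes, populations=populations)


def filter_min_sample(dataset: SpeciesDataset, min_n: int = 5) -> SpeciesDataset:
    """Retain populations with N >= ``min_n`` individuals (order preserved).

    Small samples give unstable frequency estimates; the conventional cut
    for these meta-analyses keeps populations with at least five sampled
    individuals.  Removing every population is flagged, not raised.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = [p for p in dataset.populations if p.n >= min_n]
    out = SpeciesDataset(dataset.species, dataset.haplotypes, kept)
    if not kept:
        out.empty_after_filter = True
        warnings.warn(
            f"{dataset.species}: every population removed by the N >= {min_n} filter",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# diversity statistics


def haplotype_diversity(pop: PopulationSample) -> float:
    """Nei's unbiased haplotype diversity n/(n-1) * (1 - sum p_i^2)."""
    n = pop.n
    if n < 2:
        raise UndefinedStatisticError(
            f"population {pop.pop_id!r}: H_D undefined for N={n} (< 2)"
        )
    counts = np.array(list(pop.counts.values()), dtype=float)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _pairwise_site_stats(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(differences, compared sites) between two aligned sequences.

    Pairwise deletion: positions where either sequence is not a plain base
    (gap, N or other ambiguity) are excluded from both counts.
    """
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    valid_a = np.isin(a, [c.encode() for c in _VALID_BASES])
    valid_b = np.isin(b, [c.encode() for c in _VALID_BASES])
    both = valid_a & valid_b
    ncomp = int(both.sum())
    ndiff = int(np.sum((a != b) & both))
    return ndiff, ncomp


def _distance_tables(haplotypes: list[Haplotype]) -> tuple[np.ndarray, np.ndarray]:
    """Matrices of (difference counts, compared-site counts) over the pool."""
    k = len(haplotypes)
    diffs = np.zeros((k, k), dtype=float)
    comps = np.full((k, k), len(haplotypes[0].sequence) if haplotypes else 0, dtype=float)
    for i in range(k):
        di, ci = _pairwise_site_stats(haplotypes[i].sequence, haplotypes[i].sequence)
        comps[i, i] = ci
        for j in range(i + 1, k):
            d, c = _pairwise_site_stats(haplotypes[i].sequence, haplotypes[j].sequence)
            diffs[i, j] = diffs[j, i] = d
            comps[i, j] = comps[j, i] = c
    return diffs, comps


def nucleotide_diversity(pop: PopulationSample, haplotypes: list[Haplotype]) -> float:
    """Per-site nucleotide diversity with the n/(n-1) sample-size correction.

    pi = n/(n-1) * sum_{i,j} p_i p_j d_ij where d_ij is the per-site
    proportion of differences between haplotypes i and j over their
    pairwise-comparable sites.  Pairs with zero comparable sites are
    excluded with a warning.
    """
    n = pop.n
    if n < 2:
        raise UndefinedStatisticError(
            f"population {pop.pop_id!r}: pi undefined for N={n} (< 2)"
        )
    index = {h.id: i for i, h in enumerate(haplotypes)}
    present = sorted(pop.counts)
    sub = [haplotypes[index[h]] for h in present]
    diffs, comps = _distance_tables(sub)
    counts = np.array([pop.counts[h] for h in present], dtype=float)
    p = counts / n

    total = 0.0
    for i in range(len(sub)):
        for j in range(len(sub)):
            if i == j:
                continue
            if comps[i, j] == 0:
                warnings.warn(
                    f"population {pop.pop_id!r}: haplotypes {sub[i].id!r}/{sub[j].id!r} share "
                    "no comparable sites; pair excluded from pi",
                    stacklevel=2,
                )
                continue
            total += p[i] * p[j] * diffs[i, j] / comps[i, j]
    return float(n / (n - 1) * total)


# ---------------------------------------------------------------------------
# Phi_ST (two-population AMOVA)


def _amova_distance_matrix(
    haplotypes: list[Haplotype], distance: str
) -> tuple[np.ndarray, dict[str, int]]:
    """Squared-distance matrix between haplotypes for AMOVA.

    ``distance='nucleotide'`` uses pairwise difference counts (with pairwise
    deletion of gap/N sites); ``'frequency'`` scores 1 for any two distinct
    haplotype labels, reducing Phi_ST to the frequency-only F_ST.
    """
    index = {h.id: i for i, h in enumerate(haplotypes)}
    if distance == "frequency":
        k = len(haplotypes)
        d2 = 1.0 - np.eye(k)
        return d2, index
    if distance != "nucleotide":
        raise ValueError(f"unknown distance flavor {distance!r}")
    diffs, _ = _distance_tables(haplotypes)
    return diffs, index


def _phist_from_tables(
    popA: PopulationSample,
    popB: PopulationSample,
    d2: np.ndarray,
    index: dict[str, int],
) -> float:
    for pop in (popA, popB):
        if pop.n < 2:
            raise UndefinedStatisticError(
                f"population {pop.pop_id!r}: Phi_ST undefined for N={pop.n} (< 2)"
            )

    def pop_vector(pop: PopulationSample) -> np.ndarray:
        v = np.zeros(len(index))
        for hap, c in pop.counts.items():
            v[index[hap]] = c
        return v

    va, vb = pop_vector(popA), pop_vector(popB)
    na, nb = float(popA.n), float(popB.n)
    ntot = na + nb

    def ssd(vec: np.ndarray, n: float) -> float:
        # sum over ordered individual pairs of delta^2, halved, scaled by 1/n
        return float(vec @ d2 @ vec) / (2.0 * n)

    ssd_total = ssd(va + vb, ntot)
    ssd_within = ssd(va, na) + ssd(vb, nb)
    ssd_among = ssd_total - ssd_within

    sigma2_w = ssd_within / (ntot - 2.0)
    n_c = (ntot - (na**2 + nb**2) / ntot) / 1.0  # P - 1 = 1
    sigma2_a = (ssd_among / 1.0 - sigma2_w) / n_c

    denom = sigma2_a + sigma2_w
    if denom == 0.0:
        return 0.0
    return float(sigma2_a / denom)


def pairwise_phist(
    popA: PopulationSample,
    popB: PopulationSample,
    haplotypes: list[Haplotype],
    distance: str = "nucleotide",
) -> float:
    """Phi_ST between two populations from a two-level AMOVA.

    Squared inter-individual distances are the pairwise nucleotide
    difference counts of the haplotypes the individuals carry.  Variance
    components follow the standard sums-of-squares decomposition:

        SSD_total  = (1/2N) sum_ij delta_ij^2   over all N individuals
        SSD_within = sum_pop (1/2n_p) sum_ij delta_ij^2   within each pop
        sigma2_w   = SSD_within / (N - 2)
        sigma2_a   = (SSD_among/(P-1) - sigma2_w) / n_c
        Phi_ST     = sigma2_a / (sigma2_a + sigma2_w)

    with n_c the coefficient correcting for unequal sample sizes.  Both
    populations monomorphic for the same haplotype give zero total variance;
    that degenerate case is defined as 0.0.
    """
    d2, index = _amova_distance_matrix(haplotypes, distance)
    return _phist_from_tables(popA, popB, d2, index)


def fst_matrix(dataset: SpeciesDataset, distance: str = "nucleotide") -> PairwiseFstMatrix:
    """All-pairs Phi_ST matrix over the dataset's populations.

    The haplotype distance table is computed once for the species pool and
    reused across pairs.
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise DatasetError(f"{dataset.species}: need >= 2 populations for a Phi_ST matrix")
    d2, index = _amova_distance_matrix(dataset.haplotypes, distance)
    k = len(pops)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = _phist_from_tables(pops[i], pops[j], d2, index)
            values[i, j] = values[j, i] = v
    return PairwiseFstMatrix([p.pop_id for p in pops], values)


# ---------------------------------------------------------------------------


def index_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p-value.

    Used to check agreement between diversity indices (e.g. H_D against pi)
    before dropping one of them from downstream analyses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance input")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


def diversity_table(dataset: SpeciesDataset) -> DiversityTable:
    """Per-population H_D and pi for one species, as a tidy DataFrame."""
    rows = []
    for pop in dataset.populations:
        rows.append(
            {
                "species": dataset.species,
                "pop_id": pop.pop_id,
                "lon": pop.longitude,
                "lat": pop.latitude,
                "N": pop.n,
                "H_D": haplotype_diversity(pop),
                "pi": nucleotide_diversity(pop, dataset.haplotypes),
            }
        )
    return pd.DataFrame(rows)
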