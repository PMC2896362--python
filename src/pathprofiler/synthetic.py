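"""Synthetic data with planted ground truth for every pipeline stage.

Emulates the observable outputs of a limited-sample 2-DE / MALDI-TOF
study: a protein sequence database, spot-volume tables with a planted
fraction of fold changes, tryptic peak lists with ppm jitter and shared
contaminant peaks, a pathway/interaction knowledgebase with an enriched
set planted from the differential proteins, and log-normal densitometry
replicates with a known log10 ratio R.  Every generator is deterministic
for a fixed seed; one global seed is split into independent per-generator
streams by a fixed counter scheme (``default_rng([stream_index, seed])``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as pio
from .pmf import PeakList, SearchConfig, digest, peptide_mz

#: Fixed stream indices of the per-generator child seeds.
STREAMS = {"protein_db": 0, "truth": 1, "knowledgebase": 2, "spots": 3,
           "peaks": 4, "densitometry": 5}

#: Residue frequencies loosely matching the human proteome, so tryptic
#: peptides have realistic lengths (K+R about 11%).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_WEIGHTS = np.array([
    7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
    2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.4, 6.0, 1.2, 2.7])
AA_WEIGHTS = AA_WEIGHTS / AA_WEIGHTS.sum()


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([STREAMS[stream], seed])


@dataclass
class SyntheticTruth:
    """Planted ground truth shared across the generators."""

    de_proteins: set[str]
    planted_folds: dict[str, float]         # accession -> fold (> 1)
    directions: dict[str, str]              # accession -> "A" | "B"
    spectrum_identity: dict[str, str]       # peak-list id -> accession
    enriched_pathways: set[str]
    true_R: float
    seed: int

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.planted_folds.values()):
            raise ValueError("planted folds must be >= 1")
        if set(self.planted_folds) != self.de_proteins:
            raise ValueError("planted_folds must cover de_proteins exactly")


def make_truth(accessions: list[str], n_de: int, fold: float = 2.0,
               true_R: float = 0.146, seed: int = 0) -> SyntheticTruth:
    """Pick ``n_de`` differential proteins with the given fold change.

    Directions alternate between up-in-A and up-in-B so the planted
    changes balance across the two gels, as in a real comparison where
    both conditions have up-regulated proteins.
    """
    if not 0 < n_de <= len(accessions):
        raise ValueError("n_de must be in 1..len(accessions)")
    rng = _rng("truth", seed)
    de = sorted(rng.choice(accessions, size=n_de, replace=False).tolist())
    return SyntheticTruth(
        de_proteins=set(de),
        planted_folds={acc: float(fold) for acc in de},
        directions={acc: ("A" if i % 2 == 0 else "B")
                    for i, acc in enumerate(de)},
        spectrum_identity={}, enriched_pathways=set(),
        true_R=true_R, seed=seed)


# --- protein database -------------------------------------------------------

def make_protein_db(n_proteins: int, length_range: tuple[int, int] = (100, 400),
                    seed: int = 0,
                    config: SearchConfig = SearchConfig()) -> dict[str, str]:
    """Random protein database over the 20 standard amino acids.

    Sequences are resampled until a tryptic digest yields at least one
    peptide in the instrument's m/z 800-3000 window, so every protein is
    in principle identifiable.  Accessions are SYNP0001, SYNP0002, ...
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 10:
        raise ValueError("minimum sequence length is 10")
    rng = _rng("protein_db", seed)
    db: dict[str, str] = {}
    for i in range(n_proteins):
        acc = f"SYNP{i + 1:04d}"
        while True:
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(list(AA_ALPHABET), size=length,
                                     p=AA_WEIGHTS))
            masses = [peptide_mz(p, config, 0)[0]
                      for p in digest(seq, config.missed_cleavages)]
            if any(config.mz_min <= m <= config.mz_max for m in masses):
                db[acc] = seq
                break
    return db


# --- knowledgebase ----------------------------------------------------------

def make_knowledgebase(accessions: list[str], n_pathways: int,
                       size_range: tuple[int, int], n_edges: int,
                       seed: int = 0,
                       de_proteins: set[str] | None = None,
                       planted_frac: float = 0.8,
                       community_density: float = 0.6
                       ) -> tuple[dict[str, set[str]], nx.Graph]:
    """Pathway sets and an interaction graph over the given accessions.

    Pathway members are sampled without replacement per pathway.  When
    ``de_proteins`` is given, the first pathway is planted with at least
    ``planted_frac`` of its members drawn from the differential proteins,
    and those proteins are additionally wired into a dense community of
    the graph so that both enrichment and network growth have a true
    signal to find.  The graph is simple and undirected with exactly
    ``n_edges`` edges and no self-loops.
    """
    accessions = sorted(accessions)
    lo, hi = size_range
    if n_pathways > 0 and hi > len(accessions):
        raise ValueError("pathway size exceeds the number of accessions")
    max_edges = len(accessions) * (len(accessions) - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges {n_edges} exceeds maximum {max_edges}")
    rng = _rng("knowledgebase", seed)
    de = sorted(set(de_proteins) & set(accessions)) if de_proteins else []
    non_de = [a for a in accessions if a not in set(de)]

    pathways: dict[str, set[str]] = {}
    for p in range(n_pathways):
        pid = f"PW{p + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if p == 0 and de:
            n_from_de = min(len(de), max(1, int(np.ceil(planted_frac * size))))
            members = set(rng.choice(de, size=n_from_de, replace=False))
            pool = [a for a in accessions if a not in members]
            members |= set(rng.choice(pool, size=size - len(members),
                                      replace=False))
        else:
            members = set(rng.choice(accessions, size=size, replace=False))
        pathways[pid] = members

    graph = nx.Graph()
    graph.add_nodes_from(accessions)
    edges: set[tuple[str, str]] = set()
    if de:
        community_pairs = list(itertools.combinations(de, 2))
        rng.shuffle(community_pairs)
        budget = min(len(community_pairs), n_edges,
                     int(np.ceil(community_density * len(community_pairs))))
        edges.update(tuple(sorted(e)) for e in community_pairs[:budget])
    while len(edges) < n_edges:
        a, b = rng.choice(accessions, size=2, replace=False)
        edges.add(tuple(sorted((a, b))))
    graph.add_edges_from(edges)
    return pathways, graph


# --- spot tables ------------------------------------------------------------

def make_spot_table(truth: SyntheticTruth, n_spots: int, cv: float,
                    seed: int = 0,
                    accessions: list[str] | None = None) -> pd.DataFrame:
    """Spot-volume table with planted fold changes.

    Differential proteins get a raw A/B volume ratio of their planted
    fold (in their planted direction) times multiplicative log-normal
    noise of coefficient of variation ``cv``; all other spots get ratio 1
    times noise.  The two columns are balanced to the same total volume
    by rescaling whole spots (which preserves every ratio), so that after
    total-volume normalization the recovered fold equals the planted one.
    Columns: ``spot_id, accession, raw_A, raw_B``.
    """
    if not 0 <= cv < 1:
        raise ValueError("cv must lie in [0, 1)")
    de = sorted(truth.de_proteins)
    if n_spots < len(de):
        raise ValueError("n_spots smaller than the number of de proteins")
    rng = _rng("spots", seed)
    pool = sorted(set(accessions) - set(de)) if accessions else []
    n_null = n_spots - len(de)
    if pool:
        null_accs = [pool[i % len(pool)] for i in range(n_null)]
    else:
        null_accs = [f"NULL{i + 1:04d}" for i in range(n_null)]
    accs = de + null_accs

    base = rng.lognormal(mean=np.log(1e5), sigma=0.6, size=n_spots)
    sigma_ln = np.sqrt(np.log1p(cv ** 2))
    noise = np.exp(rng.normal(0.0, sigma_ln, size=n_spots)) if cv > 0 \
        else np.ones(n_spots)
    ratio = np.ones(n_spots)
    for i, acc in enumerate(de):
        f = truth.planted_folds[acc]
        ratio[i] = f if truth.directions.get(acc, "A") == "A" else 1.0 / f
    ratio = ratio * noise
    raw_a = base * ratio
    raw_b = base.copy()

    # balance gel totals exactly, preserving per-spot ratios
    diff = raw_a - raw_b
    pos, neg = diff > 0, diff < 0
    if pos.any() and neg.any():
        t = diff[pos].sum() / -diff[neg].sum()
        raw_a[neg] *= t
        raw_b[neg] *= t
    return pd.DataFrame({
        "spot_id": [f"S{i + 1:04d}" for i in range(n_spots)],
        "accession": accs, "raw_A": raw_a, "raw_B": raw_b})


# --- peak lists -------------------------------------------------------------

def make_peak_lists(db: dict[str, str], identities: list[str],
                    detect_prob: float = 0.6, ppm_jitter: float = 15.0,
                    n_background: int = 20,
                    background_occurrence: float = 0.15,
                    seed: int = 0,
                    config: SearchConfig = SearchConfig(),
                    list_ids: list[str] | None = None
                    ) -> tuple[list[PeakList], dict[str, str]]:
    """One PMF spectrum per identity, plus shared contaminant peaks.

    Each spectrum carries a Bernoulli(``detect_prob``) subset of the
    source protein's in-window tryptic [M+H]+ masses (unmodified Met)
    with Gaussian relative mass error of scale ``ppm_jitter``, merged
    with a shared pool of ``n_background`` contaminant masses drawn
    uniformly on the m/z window, each appearing in a given spectrum with
    probability ``background_occurrence``.  Returns the batch and the
    peak-list id -> accession identity map.
    """
    if not 0 < detect_prob <= 1:
        raise ValueError("detect_prob must lie in (0, 1]")
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    unknown = [a for a in identities if a not in db]
    if unknown:
        raise KeyError(f"identities absent from database: {unknown[:5]}")
    if list_ids is None:
        list_ids = [f"PMF{i + 1:04d}" for i in range(len(identities))]
    rng = _rng("peaks", seed)
    background = rng.uniform(config.mz_min, config.mz_max,
                             size=n_background)
    batch: list[PeakList] = []
    identity: dict[str, str] = {}
    for list_id, acc in zip(list_ids, identities):
        masses = sorted({peptide_mz(p, config, 0)[0]
                         for p in digest(db[acc], config.missed_cleavages)})
        masses = np.array([m for m in masses
                           if config.mz_min <= m <= config.mz_max])
        detected = masses[rng.random(len(masses)) < detect_prob]
        if ppm_jitter > 0:
            detected = detected * (
                1.0 + rng.normal(0.0, ppm_jitter * 1e-6, len(detected)))
        contam = background[rng.random(n_background)
                            < background_occurrence]
        mz = np.concatenate([detected, contam])
        intensity = rng.lognormal(mean=np.log(500.0), sigma=0.7,
                                  size=len(mz))
        batch.append(PeakList(list_id, mz, intensity))
        identity[list_id] = acc
    return batch, identity


# --- densitometry -----------------------------------------------------------

def make_densitometry(true_R: float, sigma: float, n_replicates: int,
                      seed: int = 0) -> pd.DataFrame:
    """Densitometry replicates with a known log10 expression ratio.

    Target and loading-control band densities are log-normal; per
    replicate the loading-normalized log10 ratio between conditions is
    exactly Normal(true_R, sigma^2) by construction, so the generating R
    is recoverable.  Columns: ``replicate, condition, target_density,
    loading_density``.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates (variance undefined)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = _rng("densitometry", seed)
    rows = []
    for i in range(n_replicates):
        loading_a = rng.lognormal(np.log(1000.0), 0.3)
        loading_b = rng.lognormal(np.log(1000.0), 0.3)
        baseline = rng.normal(0.0, 0.2)     # per-replicate blot level
        y = true_R + sigma * rng.standard_normal()
        rows.append({"replicate": i + 1, "condition": "A",
                     "target_density": loading_a * 10.0 ** (baseline + y),
                     "loading_density": loading_a})
        rows.append({"replicate": i + 1, "condition": "B",
                     "target_density": loading_b * 10.0 ** baseline,
                     "loading_density": loading_b})
    return pd.DataFrame(rows)


# --- full dataset -----------------------------------------------------------

@dataclass
class DatasetPaths:
    fasta: Path
    gmt: Path
    sif: Path
    spots: Path
    mgf: Path
    densitometry: Path
    truth: Path


def generate_dataset(outdir: str | Path, seed: int = 0,
                     n_proteins: int = 100, n_spots: int = 200,
                     n_de: int = 20, fold: float = 2.0, cv: float = 0.1,
                     detect_prob: float = 0.6, ppm_jitter: float = 15.0,
                     n_background: int = 20,
                     background_occurrence: float = 0.15,
                     n_pathways: int = 15,
                     pathway_size: tuple[int, int] = (4, 12),
                     n_edges: int = 400, true_R: float = 0.146,
                     densitometry_sigma: float = 0.05,
                     n_replicates: int = 6,
                     config: SearchConfig = SearchConfig()
                     ) -> tuple[DatasetPaths, SyntheticTruth]:
    """Generate every input file the pipeline consumes, with truth sidecar.

    Defaults are the desk-scale study conditions: a 100-protein database,
    200 matched spots of which 10% carry a 2-fold change at 10% volume
    CV, spectra at 60% peptide detection with 15 ppm jitter and a shared
    contaminant pool at 15% occurrence, a 15-pathway knowledgebase with
    one planted enriched pathway, and 6 densitometry replicates at
    R = 0.146 (about 1.4-fold).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = make_protein_db(n_proteins, seed=seed, config=config)
    accessions = sorted(db)
    truth = make_truth(accessions, n_de=n_de, fold=fold, true_R=true_R,
                       seed=seed)
    pathways, graph = make_knowledgebase(
        accessions, n_pathways, pathway_size, n_edges, seed=seed,
        de_proteins=truth.de_proteins)
    truth.enriched_pathways = {"PW001"} if pathways and \
        truth.de_proteins else set()
    spots = make_spot_table(truth, n_spots, cv, seed=seed,
                            accessions=accessions)
    batch, identity = make_peak_lists(
        db, spots["accession"].tolist(), detect_prob, ppm_jitter,
        n_background, background_occurrence, seed=seed, config=config,
        list_ids=spots["spot_id"].tolist())
    truth.spectrum_identity = identity
    densitometry = make_densitometry(true_R, densitometry_sigma,
                                     n_replicates, seed=seed)

    paths = DatasetPaths(
        fasta=outdir / "proteins.fasta", gmt=outdir / "pathways.gmt",
        sif=outdir / "interactions.sif", spots=outdir / "spots.csv",
        mgf=outdir / "spectra.mgf",
        densitometry=outdir / "densitometry.csv",
        truth=outdir / "truth.json")
    pio.write_fasta(db, paths.fasta)
    pio.write_gmt(pathways, paths.gmt)
    pio.write_sif(graph, paths.sif)
    spots.to_csv(paths.spots, index=False)
    pio.write_mgf(batch, paths.mgf)
    densitometry.to_csv(paths.densitometry, index=False)
    pio.write_truth(truth, paths.truth)
    return paths, truth
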