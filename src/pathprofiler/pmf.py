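"""Peptide-mass-fingerprint (PMF) protein identification.

A tryptic digest of a 2-DE spot yields a set of peptide masses (the
fingerprint).  Identification matches the observed monoisotopic [M+H]+
masses against in-silico digests of every protein in a sequence database
within a ppm tolerance, scores each candidate with three independent
scoring schemes, and calls a consensus identification when a candidate
ranks high in at least two of the three.  A batch-level background filter
removes contaminant peaks (keratin, trypsin autolysis, matrix) that recur
across many spectra, and an Mr/pI plausibility check compares the
candidate's theoretical gel coordinates with the observed ones.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# --- physical constants -----------------------------------------------------

#: Monoisotopic residue masses (Da), standard IUPAC values at 5 decimals.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

#: Cys alkylation products: iodoacetamide yields carbamidomethyl;
#: iodoacetic acid yields carboxymethyl.  Both selectable in SearchConfig.
CARBAMIDOMETHYL = 57.02146
CARBOXYMETHYL = 58.00548
MET_OXIDATION = 15.9949

#: Bjellqvist pKa values used for the theoretical isoelectric point.
PKA_BJELLQVIST = {
    "nterm": 7.50, "cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,   # acidic side chains
    "H": 5.98, "K": 10.00, "R": 12.00,             # basic side chains
}

ACIDIC = ("D", "E", "C", "Y")
BASIC = ("H", "K", "R")


# --- containers -------------------------------------------------------------

@dataclass
class PeakList:
    """One PMF spectrum: sorted m/z values with positive intensities."""

    list_id: str
    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] = (800.0, 3000.0)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        lo, hi = self.window
        keep = (self.mz >= lo) & (self.mz <= hi)
        self.mz = self.mz[keep]
        self.intensity = self.intensity[keep]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class SearchConfig:
    """Database-search settings.

    Defaults are the standard PMF search settings: 50 ppm tolerance, one
    missed tryptic cleavage, fixed Cys carbamidomethylation, variable Met
    oxidation, singly protonated monoisotopic masses in m/z 800-3000.
    """

    tolerance_ppm: float = 50.0
    missed_cleavages: int = 1
    cys_mod: float = CARBAMIDOMETHYL
    variable_met_ox: bool = True
    mz_min: float = 800.0
    mz_max: float = 3000.0
    r_top: int = 5          # "ranked high" = rank <= r_top
    min_batch: int = 10     # background filter refuses smaller batches
    bin_tolerance_ppm: float = 100.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass
class PMFIdentification:
    """Scores and ranks of one candidate protein for one peak list."""

    list_id: str
    accession: str
    matched: int
    coverage_pct: float
    score1: float   # shared-peak count
    score2: float   # sequence coverage (%)
    score3: float   # rarity-weighted peak score
    rank1: int = 0
    rank2: int = 0
    rank3: int = 0
    consensus: bool = False
    mr_pi_ok: bool | None = None


# --- digestion and masses ---------------------------------------------------

def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in MONOISOTOPIC:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """In-silico tryptic digest under the Keil rule.

    Cleaves C-terminal to K or R except when the next residue is P.
    Returns all products with 0..missed_cleavages internal missed sites,
    grouped by missed-cleavage count, each group in N-to-C order.
    Duplicate sequences are retained.
    """
    _check_sequence(sequence)
    if not sequence:
        return []
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    fragments = [sequence[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
    peptides: list[str] = []
    for mc in range(missed_cleavages + 1):
        for start in range(len(fragments) - mc):
            peptides.append("".join(fragments[start:start + mc + 1]))
    return peptides


def peptide_mz(peptide: str, config: SearchConfig = SearchConfig(),
               n_oxidized_met: int | None = None) -> list[float]:
    """Monoisotopic [M+H]+ m/z values of a peptide.

    With ``n_oxidized_met=None`` and variable Met oxidation enabled, one
    mass is returned per oxidation count 0..#Met; otherwise a single mass
    at the requested oxidation count.  The fixed Cys modification is
    always applied.
    """
    _check_sequence(peptide)
    base = sum(MONOISOTOPIC[aa] for aa in peptide) + WATER + PROTON
    base += config.cys_mod * peptide.count("C")
    n_met = peptide.count("M")
    if n_oxidized_met is not None:
        if n_oxidized_met > n_met:
            raise ValueError(
                f"{n_oxidized_met} oxidations requested but peptide has "
                f"{n_met} Met")
        return [base + MET_OXIDATION * n_oxidized_met]
    counts = range(n_met + 1) if config.variable_met_ox else (0,)
    return [base + MET_OXIDATION * k for k in counts]


@dataclass(frozen=True)
class TheoreticalPeptide:
    mz: float
    peptide: str
    start: int      # 0-based residue span in the parent sequence
    end: int        # exclusive
    n_ox: int


def theoretical_peptides(sequence: str,
                         config: SearchConfig = SearchConfig()
                         ) -> list[TheoreticalPeptide]:
    """All in-window theoretical [M+H]+ masses of a protein, with the
    residue span each mass covers (used for sequence coverage)."""
    _check_sequence(sequence)
    out: list[TheoreticalPeptide] = []
    # recompute spans: digest() loses positions, so walk fragments here
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    for mc in range(config.missed_cleavages + 1):
        for s in range(len(cuts) - 1 - mc):
            start, end = cuts[s], cuts[s + mc + 1]
            pep = sequence[start:end]
            for n_ox, mz in enumerate(peptide_mz(pep, config)):
                if config.mz_min <= mz <= config.mz_max:
                    out.append(TheoreticalPeptide(mz, pep, start, end, n_ox))
    out.sort(key=lambda t: t.mz)
    return out


# --- matching ---------------------------------------------------------------

def match_peaks(peaks: PeakList, theoretical: list[float],
                tolerance_ppm: float = 50.0) -> list[tuple[int, int]]:
    """Match observed peaks to theoretical masses within a ppm window.

    Each observed peak matches at most one theoretical mass: the one at
    the smallest ppm error, ties resolved toward the lower m/z.  The
    match is inclusive at the tolerance boundary.  Returns (peak index,
    theoretical index) pairs.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    order = sorted(range(len(theoretical)), key=lambda i: theoretical[i])
    sorted_mz = [theoretical[i] for i in order]
    pairs: list[tuple[int, int]] = []
    for pi, obs in enumerate(peaks.mz):
        j = bisect.bisect_left(sorted_mz, obs)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(sorted_mz):
                theo = sorted_mz[cand]
                ppm = abs(obs - theo) / theo * 1e6
                if ppm <= tolerance_ppm:
                    key = (ppm, theo)
                    if best is None or key < best[0]:
                        best = (key, order[cand])
        if best is not None:
            pairs.append((pi, best[1]))
    return pairs


# --- background filtering ---------------------------------------------------

def _cluster_mz(values: np.ndarray, bin_tolerance_ppm: float) -> np.ndarray:
    """Single-linkage 1-D clustering: a new bin starts wherever the gap to
    the previous (sorted) value exceeds the ppm tolerance."""
    if len(values) == 0:
        return np.array([], dtype=int)
    order = np.argsort(values)
    sv = values[order]
    labels_sorted = np.zeros(len(sv), dtype=int)
    current = 0
    for i in range(1, len(sv)):
        if (sv[i] - sv[i - 1]) / sv[i - 1] * 1e6 > bin_tolerance_ppm:
            current += 1
        labels_sorted[i] = current
    labels = np.empty(len(sv), dtype=int)
    labels[order] = labels_sorted
    return labels


def filter_background(batch: list[PeakList],
                      occurrence_threshold: float = 0.10,
                      bin_tolerance_ppm: float = 100.0,
                      min_batch: int = 10
                      ) -> tuple[list[PeakList], pd.DataFrame]:
    """Remove contaminant peaks that recur across a batch of spectra.

    All peaks in the batch are clustered on m/z (single linkage at
    ``bin_tolerance_ppm``); any bin observed in strictly more than
    ``occurrence_threshold`` of the lists is deleted from every list.
    Returns the filtered batch and a report of removed bins with their
    occurrence fractions.  Refuses batches smaller than ``min_batch``,
    where an occurrence fraction is meaningless.
    """
    if len(batch) < min_batch:
        raise ValueError(
            f"background filter needs >= {min_batch} peak lists, "
            f"got {len(batch)}")
    all_mz = np.concatenate([pl.mz for pl in batch]) if batch else np.array([])
    owner = np.concatenate([np.full(len(pl), i) for i, pl in enumerate(batch)])
    labels = _cluster_mz(all_mz, bin_tolerance_ppm)
    n_lists = len(batch)
    removed_rows = []
    drop = np.zeros(len(all_mz), dtype=bool)
    for lab in np.unique(labels):
        sel = labels == lab
        frac = len(np.unique(owner[sel])) / n_lists
        if frac > occurrence_threshold:
            drop[sel] = True
            removed_rows.append({
                "bin_mz": float(np.mean(all_mz[sel])),
                "n_lists": int(len(np.unique(owner[sel]))),
                "occurrence": frac,
            })
    filtered: list[PeakList] = []
    offset = 0
    for pl in batch:
        keep = ~drop[offset:offset + len(pl)]
        offset += len(pl)
        filtered.append(PeakList(pl.list_id, pl.mz[keep], pl.intensity[keep],
                                 window=pl.window))
    report = pd.DataFrame(removed_rows,
                          columns=["bin_mz", "n_lists", "occurrence"])
    return filtered, report.sort_values("bin_mz").reset_index(drop=True)


# --- scoring ----------------------------------------------------------------

class DigestIndex:
    """Precomputed in-silico digests of a protein database plus the global
    100 Da mass-bin frequencies used by the rarity-weighted scorer."""

    BIN_DA = 100.0

    def __init__(self, db: dict[str, str],
                 config: SearchConfig = SearchConfig()) -> None:
        if not db:
            raise ValueError("protein database is empty")
        self.config = config
        self.accessions = sorted(db)
        self.entries = {acc: theoretical_peptides(db[acc], config)
                        for acc in self.accessions}
        self.lengths = {acc: len(db[acc]) for acc in self.accessions}
        self._bin_counts: dict[int, int] = {}
        total = 0
        for ents in self.entries.values():
            for t in ents:
                b = int(t.mz // self.BIN_DA)
                self._bin_counts[b] = self._bin_counts.get(b, 0) + 1
                total += 1
        self._total = max(total, 1)

    def rarity(self, mz: float) -> float:
        """-log10 of the fraction of all database peptide masses falling
        in this mass's 100 Da bin."""
        count = self._bin_counts.get(int(mz // self.BIN_DA), 1)
        return -np.log10(count / self._total)


def _dense_ranks(scores: dict[str, float]) -> dict[str, int]:
    """Dense ranking, highest score = rank 1; equal scores share a rank."""
    distinct = sorted(set(scores.values()), reverse=True)
    level = {s: i + 1 for i, s in enumerate(distinct)}
    return {acc: level[s] for acc, s in scores.items()}


def score_candidates(peaks: PeakList, db: dict[str, str] | DigestIndex,
                     config: SearchConfig = SearchConfig()
                     ) -> list[PMFIdentification]:
    """Score every database protein against one peak list.

    Three scoring schemes stand in for the commercial search engines:
    scorer 1 counts shared peaks, scorer 2 is percent sequence coverage,
    scorer 3 weights each matched peptide by how rare its 100 Da mass bin
    is across the whole database.  Ranks are dense per scorer;
    ``consensus`` is true when the candidate ranks <= r_top in at least
    two of the three.  Candidates are returned sorted by rank sum then
    accession.
    """
    index = db if isinstance(db, DigestIndex) else DigestIndex(db, config)
    results: list[PMFIdentification] = []
    for acc in index.accessions:
        ents = index.entries[acc]
        pairs = match_peaks(peaks, [t.mz for t in ents], config.tolerance_ppm)
        covered = np.zeros(index.lengths[acc], dtype=bool)
        matched_entries = {ti for _, ti in pairs}
        for ti in matched_entries:
            covered[ents[ti].start:ents[ti].end] = True
        coverage = 100.0 * covered.mean() if len(covered) else 0.0
        score3 = float(sum(index.rarity(ents[ti].mz)
                           for ti in matched_entries))
        results.append(PMFIdentification(
            list_id=peaks.list_id, accession=acc, matched=len(pairs),
            coverage_pct=float(coverage), score1=float(len(pairs)),
            score2=float(coverage), score3=score3))
    for attr, rattr in (("score1", "rank1"), ("score2", "rank2"),
                        ("score3", "rank3")):
        ranks = _dense_ranks({r.accession: getattr(r, attr) for r in results})
        for r in results:
            setattr(r, rattr, ranks[r.accession])
    for r in results:
        high = sum(rk <= config.r_top for rk in (r.rank1, r.rank2, r.rank3))
        r.consensus = high >= 2 and r.matched > 0
    results.sort(key=lambda r: (r.rank1 + r.rank2 + r.rank3, r.accession))
    return results


def best_identification(peaks: PeakList, db: dict[str, str] | DigestIndex,
                        config: SearchConfig = SearchConfig()
                        ) -> PMFIdentification | None:
    """Best consensus candidate for one peak list, or None when no
    candidate reaches consensus (including the empty-spectrum case)."""
    if len(peaks) == 0:
        return None
    for cand in score_candidates(peaks, db, config):
        if cand.consensus:
            return cand
    return None


def identify_batch(batch: list[PeakList], db: dict[str, str],
                   config: SearchConfig = SearchConfig()) -> pd.DataFrame:
    """Identification report for a batch: one row per peak list with the
    best consensus candidate (accession empty when none)."""
    index = DigestIndex(db, config)
    rows = []
    for pl in batch:
        best = best_identification(pl, index, config)
        if best is None:
            rows.append({"list_id": pl.list_id, "accession": "",
                         "matched": 0, "coverage_pct": 0.0,
                         "score1": 0.0, "score2": 0.0, "score3": 0.0,
                         "rank1": 0, "rank2": 0, "rank3": 0,
                         "consensus": False})
        else:
            rows.append({
                "list_id": best.list_id, "accession": best.accession,
                "matched": best.matched, "coverage_pct": best.coverage_pct,
                "score1": best.score1, "score2": best.score2,
                "score3": best.score3, "rank1": best.rank1,
                "rank2": best.rank2, "rank3": best.rank3,
                "consensus": best.consensus})
    return pd.DataFrame(rows)


# --- Mr / pI plausibility ---------------------------------------------------

def protein_mr_kda(sequence: str) -> float:
    """Theoretical monoisotopic molecular mass in kDa."""
    _check_sequence(sequence)
    return (sum(MONOISOTOPIC[aa] for aa in sequence) + WATER) / 1000.0


def net_charge(sequence: str, ph: float,
               pka: dict[str, float] = PKA_BJELLQVIST) -> float:
    """Net charge at a given pH by the Henderson-Hasselbalch sum over the
    termini and the D,E,C,Y,H,K,R side chains."""
    _check_sequence(sequence)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["cterm"] - ph))
    for aa in BASIC:
        if aa in pka:
            charge += sequence.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in ACIDIC:
        if aa in pka:
            charge -= sequence.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(sequence: str,
                      pka: dict[str, float] = PKA_BJELLQVIST,
                      tol: float = 1e-6) -> float:
    """Theoretical pI: the unique root of the strictly decreasing
    net-charge function, located by bisection on pH 0..14."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def check_mr_pi(accession: str, observed_mr_kda: float, observed_pi: float,
                db: dict[str, str], mr_rel_tol: float = 0.20,
                pi_tol: float = 1.0) -> bool:
    """Gel-coordinate plausibility: observed Mr within 20% relative and
    observed pI within 1.0 unit of the candidate's theoretical values."""
    if accession not in db:
        raise KeyError(f"accession {accession!r} not in database")
    seq = db[accession]
    theo_mr = protein_mr_kda(seq)
    theo_pi = isoelectric_point(seq)
    mr_ok = abs(theo_mr - observed_mr_kda) <= mr_rel_tol * theo_mr
    pi_ok = abs(theo_pi - observed_pi) <= pi_tol
    return bool(mr_ok and pi_ok)
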