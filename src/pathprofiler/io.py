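"""Readers and writers for the pipeline's file formats.

FASTA (protein database, via Biopython), GMT (tab-delimited gene sets),
SIF/TSV (interaction edges), MGF and two-column text (peak lists, via
pyteomics for MGF), and the CSV tables for spot volumes, densitometry and
expression matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .pmf import PeakList

SPOT_COLUMNS = ["spot_id", "raw_A", "raw_B"]
DENSITOMETRY_COLUMNS = ["replicate", "condition", "target_density",
                        "loading_density"]


# --- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein database as an accession -> sequence mapping."""
    db = {rec.id: str(rec.seq).upper()
          for rec in SeqIO.parse(str(path), "fasta")}
    if not db:
        raise ValueError(f"no FASTA records in {path}")
    return db


def write_fasta(db: dict[str, str], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    records = [SeqRecord(Seq(seq), id=acc,
                         description=(descriptions or {}).get(acc, ""))
               for acc, seq in db.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GMT --------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets: pathway id -> member accessions (description dropped)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sets):
            desc = (descriptions or {}).get(pid, "na")
            members = "\t".join(sorted(sets[pid]))
            fh.write(f"{pid}\t{desc}\t{members}\n" if members
                     else f"{pid}\t{desc}\n")


# --- SIF / TSV edges --------------------------------------------------------

def read_sif(path: str | Path) -> nx.Graph:
    """Undirected simple interaction graph from node TAB node lines."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            a, b = fields
        elif len(fields) == 3:     # classic SIF: node, relation, node
            a, _, b = fields
        else:
            raise ValueError(f"malformed SIF line: {line!r}")
        if a != b:
            graph.add_edge(a, b)
    return graph


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# --- peak lists -------------------------------------------------------------

def read_mgf(path: str | Path) -> list[PeakList]:
    batch = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            list_id = spec["params"].get("title", f"spectrum_{i}")
            batch.append(PeakList(str(list_id), spec["m/z array"],
                                  spec["intensity array"]))
    return batch


def write_mgf(batch: list[PeakList], path: str | Path) -> None:
    spectra = [{"m/z array": pl.mz, "intensity array": pl.intensity,
                "params": {"title": pl.list_id, "pepmass": (0.0, None)}}
               for pl in batch]
    _mgf.write(spectra, output=str(path), file_mode="w")


def read_peaklist_txt(path: str | Path, list_id: str | None = None
                      ) -> PeakList:
    """Two-column (m/z, intensity) whitespace- or comma-separated text."""
    data = pd.read_csv(path, sep=None, engine="python", header=None,
                       comment="#")
    if data.shape[1] < 2:
        raise ValueError(f"expected two columns in {path}")
    return PeakList(list_id or Path(path).stem,
                    data.iloc[:, 0].to_numpy(float),
                    data.iloc[:, 1].to_numpy(float))


def write_peaklist_txt(peaks: PeakList, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([peaks.mz, peaks.intensity]),
               fmt="%.6f\t%.4f")


# --- CSV tables -------------------------------------------------------------

def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot table missing columns {missing}")
    return df


def read_densitometry(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"densitometry table missing columns {missing}")
    return df


def read_focus_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_focus_list(focus: list[str] | set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{acc}\n" for acc in sorted(focus)))


# --- truth sidecar ----------------------------------------------------------

def write_truth(truth, path: str | Path) -> None:
    from .synthetic import SyntheticTruth
    assert isinstance(truth, SyntheticTruth)
    payload = {
        "de_proteins": sorted(truth.de_proteins),
        "planted_folds": truth.planted_folds,
        "directions": truth.directions,
        "spectrum_identity": truth.spectrum_identity,
        "enriched_pathways": sorted(truth.enriched_pathways),
        "true_R": truth.true_R,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path):
    from .synthetic import SyntheticTruth
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        de_proteins=set(payload["de_proteins"]),
        planted_folds={k: float(v)
                       for k, v in payload["planted_folds"].items()},
        directions=dict(payload["directions"]),
        spectrum_identity=dict(payload["spectrum_identity"]),
        enriched_pathways=set(payload["enriched_pathways"]),
        true_R=float(payload["true_R"]),
        seed=int(payload["seed"]),
    )
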