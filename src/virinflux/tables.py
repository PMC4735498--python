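"""Tabular (TSV) exports of evidence, junctions, clusters, logos, coverage
profiles and synthetic-data bundles."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import write_fasta
from .chimera import JunctionEvidence
from .junctions import Junction, JunctionCluster, LogoMatrix
from .synth import Population, SimulationConfig


def evidence_table(evidence: Sequence[JunctionEvidence]) -> pd.DataFrame:
    rows = []
    for e in evidence:
        rows.append(
            {
                "read_id": e.read_id,
                "mate": e.mate,
                "library": e.library_id,
                "kind": e.kind,
                "virus_start": e.virus_aln.subject_start,
                "virus_end": e.virus_aln.subject_end,
                "virus_strand": e.virus_strand,
                "contig": e.host_id,
                "contig_start": e.host_aln.subject_start,
                "contig_end": e.host_aln.subject_end,
                "contig_strand": e.host_strand,
                "virus_only_len": e.virus_only_len,
                "host_only_len": e.host_only_len,
                "overlap": e.overlap_len,
                "offset": e.offset,
            }
        )
    return pd.DataFrame(rows)


def junction_table(junctions: Sequence[Junction]) -> pd.DataFrame:
    rows = []
    for j in junctions:
        rows.append(
            {
                "contig": j.contig_id,
                "offset": j.offset,
                "virus_strand": j.virus_strand,
                "host_strand": j.host_strand,
                "library_scope": j.library_scope or "",
                "virus_position": j.virus_position,
                "contig_position": j.contig_position,
                "side": j.side,
                "read_count": j.read_count,
                "mechanism": j.mechanism,
                "microhomology_length": j.microhomology_length,
            }
        )
    return pd.DataFrame(rows)


def cluster_table(clusters: Sequence[JunctionCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig_id,
                "contig_end_position": c.contig_end_position,
                "side": c.side,
                "n_junctions": len(c.members),
                "n_distinct_virus_sites": c.n_distinct_virus_sites,
            }
            for c in clusters
        ]
    )


def logo_table(logo: LogoMatrix) -> pd.DataFrame:
    df = pd.DataFrame(logo.frequencies, columns=list("ACGT"))
    df.insert(0, "position", np.arange(logo.width))
    df["information_bits"] = logo.information
    return df


def coverage_table(
    profiles: dict[str, np.ndarray],
    contig_id: str,
    contig_length: int,
    window: int = 20,
    step: int = 10,
) -> pd.DataFrame:
    """BED-like per-window depth rows: contig, start, end, class, depth."""
    rows = []
    for cls, depths in profiles.items():
        for i, d in enumerate(depths):
            lo = i * step
            rows.append(
                {
                    "contig": contig_id,
                    "start": lo,
                    "end": min(lo + window, contig_length),
                    "class": cls,
                    "depth": float(d),
                }
            )
    return pd.DataFrame(rows)


def write_population(
    population: Population, config: SimulationConfig, outdir
) -> dict[str, Path]:
    """Write the synthetic bundle: genome and contig FASTA, contig
    annotations, the insertion truth table and the flat config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "contigs": out / "contigs.fasta",
        "annotations": out / "contigs.tsv",
        "truth": out / "truth_insertions.tsv",
        "config": out / "config.txt",
    }
    write_fasta({"virus": population.reference.sequence}, paths["genome"])
    write_fasta(
        {c.contig_id: c.sequence for c in population.contigs}, paths["contigs"]
    )
    pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "class": c.contig_class,
                "family": c.family or "",
                "target_motif": c.target_motif or "",
                "tir_length": c.tir_length,
                "length": len(c.sequence),
            }
            for c in population.contigs
        ]
    ).to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "genome_id": t.genome_id,
                "mechanism": t.mechanism,
                "virus_site": t.virus_site,
                "contig_id": t.contig_id,
                "contig_start": t.contig_interval[0],
                "contig_end": t.contig_interval[1],
                "orientation": t.orientation,
                "microhomology_length": t.microhomology_length,
                "tsd_length": t.tsd_length,
            }
            for t in population.truth
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}\t{getattr(config, f.name)}\n")
    return paths
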