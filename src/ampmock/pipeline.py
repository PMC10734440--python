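"""End-to-end pipeline: simulate libraries, evaluate them, write reports.

`run_simulate` produces paired FASTQ + truth sidecars for a grid of
(community x method x replicate); `run_evaluate` runs trim -> merge ->
chimera accounting -> error grid -> rarefied OTU clustering -> artifact
classification -> bias statistics and writes TSV reports. Every output
table carries the config hash in a header comment; all randomness flows
from one seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import chimera as chim
from . import errors as err
from . import otu as otu_mod
from . import qc, simulate, stats
from .design import MockDesign
from .io import write_tsv
from .qc import ReadRecord

log = logging.getLogger("ampmock")


@dataclass
class RunConfig:
    communities: list[str] = field(default_factory=lambda: ["Bm1", "Bm2", "Bm3"])
    methods: list[str] = field(default_factory=lambda: list(simulate.METHODS))
    replicates: int = 3
    n_reads: int = 600
    seed: int = 0
    strain_seed: int = 0
    contaminant_rate: float = 0.01
    n_contaminants: int = 12
    trim_grid: list[str] = field(default_factory=lambda: list(qc.TRIM_GRID))
    chimera_mode: str = "balanced"
    rarefaction_depth: Optional[int] = None  # None -> smallest library
    otu_trim_level: str = "Q20-W5"
    otu_min_len: int = 200
    #: communities whose libraries enter the error grid (first replicate each)
    error_grid_communities: list[str] = field(default_factory=lambda: ["Bm1"])
    error_grid_max_reads: int = 300

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha1(yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SimulationBundle:
    strains: list
    designs: dict[str, MockDesign]
    contaminants: dict[str, str]
    external_db: dict[str, str]
    libraries: dict[str, simulate.SimulatedLibrary]

    def mock_refs(self) -> dict[str, str]:
        return {s.strain_id: s.v4_seq for s in self.strains if s.v4_seq}


def make_external_db(strains, seed: int = 2, n_exact: int = 7,
                     n_missing: int = 4) -> dict[str, str]:
    """Synthetic stand-in for an external 16S database.

    Holds a close (98-99.8% identical) relative of most mock strains, an
    identical match for ``n_exact`` of them, and no relative at all for
    ``n_missing`` — the gap that makes some true chimeras undetectable by
    database-guided filtering.
    """
    rng = np.random.default_rng(seed)
    usable = [s for s in strains if s.v4_seq]
    missing = set(rng.choice([s.strain_id for s in usable], size=n_missing, replace=False))
    exact = set(rng.choice([s.strain_id for s in usable if s.strain_id not in missing],
                           size=n_exact, replace=False))
    db: dict[str, str] = {}
    for s in usable:
        if s.strain_id in missing:
            continue
        name = f"DB_{s.strain_id}"
        if s.strain_id in exact:
            db[name] = s.v4_seq
        else:
            div = rng.uniform(0.002, 0.02)
            n_mut = max(1, int(rng.binomial(len(s.v4_seq), div)))
            db[name] = simulate._mutate(s.v4_seq, n_mut, rng)
    return db


def run_simulate(config: RunConfig, outdir: Optional[str | Path] = None) -> SimulationBundle:
    """Simulate all configured libraries; optionally write FASTQ/TSV to disk."""
    strains = simulate.make_mock_strains(seed=config.strain_seed)
    designs = simulate.standard_communities(strains)
    contaminants = simulate.make_contaminants(config.n_contaminants,
                                              seed=config.strain_seed + 1,
                                              mock_strains=strains)
    external_db = make_external_db(strains, seed=config.strain_seed + 2)
    root = np.random.default_rng(config.seed)
    libraries: dict[str, simulate.SimulatedLibrary] = {}
    for comm in config.communities:
        if comm not in designs:
            raise ValueError(f"unknown community {comm!r}")
        for method in config.methods:
            params = simulate.method_params(method,
                                            contaminant_rate=config.contaminant_rate)
            for rep in range(1, config.replicates + 1):
                lib_id = f"{comm}.{method}.rep{rep}"
                lib_seed = int(root.integers(0, 2**31))
                lib = simulate.simulate_library(designs[comm], params, config.n_reads,
                                                lib_id, contaminants, seed=lib_seed)
                libraries[lib_id] = lib
                log.info("simulated %s (%d read pairs)", lib_id, len(lib.fwd))
    bundle = SimulationBundle(strains, designs, contaminants, external_db, libraries)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"config_hash={config.config_hash()}"
        from .io import write_fasta
        write_fasta(bundle.mock_refs(), outdir / "mock_refs.fasta")
        write_fasta(external_db, outdir / "external_db.fasta")
        write_fasta(contaminants, outdir / "contaminants.fasta")
        for name, design in designs.items():
            if name in config.communities:
                design.write_tsv(outdir / f"design_{name}.tsv", header_comment=header)
        for lib in libraries.values():
            lib.write(outdir / "libraries")
        config.to_yaml(outdir / "config.yaml")
    return bundle


def _to_read_records(reads, mate: str) -> list[ReadRecord]:
    return [ReadRecord(rid, seq, quals, mate) for rid, seq, quals in reads]


@dataclass
class EvaluationBundle:
    chimera_table: pd.DataFrame
    error_table: pd.DataFrame
    otu_tables: dict[str, otu_mod.OtuTable]
    spurious_tables: dict[str, pd.DataFrame]
    bias_reports: dict[str, stats.BiasReport]
    confusion: Optional[pd.DataFrame] = None


def run_evaluate(config: RunConfig, bundle: SimulationBundle,
                 outdir: Optional[str | Path] = None) -> EvaluationBundle:
    """Evaluate simulated (or loaded) libraries end to end."""
    mock_refs = bundle.mock_refs()
    db_refs = bundle.external_db
    mode = config.chimera_mode
    header = f"config_hash={config.config_hash()}"

    # --- chimera accounting on raw merged reads, per library
    chim_rows = []
    detected_ids: set[str] = set()
    truth_by_read = {}
    merged_raw: dict[str, list[ReadRecord]] = {}
    for lib_id, lib in sorted(bundle.libraries.items()):
        for t in lib.truth:
            truth_by_read[t.read_id] = t
        fwd = _to_read_records(lib.fwd, "fwd")
        rev = _to_read_records(lib.rev, "rev")
        merged, _ = qc.process_pairs(fwd, rev, level="raw", min_len=100,
                                     library_id=lib_id)
        merged_raw[lib_id] = merged
        pairs = [(r.read_id, r.seq) for r in merged]
        acc, true_calls, det_calls = chim.chimera_accounting(pairs, mock_refs, db_refs,
                                                             mode=mode)
        detected_ids |= {rid for rid, c in det_calls.items() if c.is_chimera}
        comm, method, rep = lib_id.split(".")
        truth_chim = {r.read_id for r in merged
                      if truth_by_read[r.read_id].origin == "chimera"}
        called_true = {rid for rid, c in true_calls.items() if c.is_chimera}
        clean_chim = {r.read_id for r in merged
                      if truth_by_read[r.read_id].origin == "chimera"
                      and truth_by_read[r.read_id].n_pcr_substitutions == 0
                      and truth_by_read[r.read_id].n_seq_substitutions == 0}
        chim_rows.append({
            "library": lib_id, "community": comm, "method": method,
            "n_reads": acc.n_reads, "n_true": acc.n_true,
            "n_detected": acc.n_detected, "n_undetected": acc.n_undetected,
            "rate_true": acc.rate_true, "rate_detected": acc.rate_detected,
            "rate_undetected": acc.rate_undetected,
            "gc_chimeric_mean": acc.gc_chimeric_mean,
            "gc_non_chimeric_mean": acc.gc_non_chimeric_mean,
            "n_truth_chimera": len(truth_chim),
            "truth_recall": (len(truth_chim & called_true) / len(truth_chim)
                             if truth_chim else np.nan),
            "clean_truth_recall": (len(clean_chim & called_true) / len(clean_chim)
                                   if clean_chim else np.nan),
        })
        log.info("chimera accounting %s: true %.2f%%, detected %.2f%%", lib_id,
                 acc.rate_true, acc.rate_detected)
    chimera_table = pd.DataFrame(chim_rows)

    # --- error grid on a subset of libraries
    grid_libs = {}
    seen_methods = set()
    for lib_id, lib in sorted(bundle.libraries.items()):
        comm, method, rep = lib_id.split(".")
        if comm in config.error_grid_communities and (comm, method) not in seen_methods:
            seen_methods.add((comm, method))
            k = config.error_grid_max_reads
            grid_libs[lib_id] = {
                "fwd": _to_read_records(lib.fwd[:k], "fwd"),
                "rev": _to_read_records(lib.rev[:k], "rev"),
            }
    error_table, _profiles = err.error_grid(grid_libs, mock_refs,
                                            trim_grid=config.trim_grid,
                                            chimera_read_ids=detected_ids)

    # --- OTU pipeline per community (rarefy -> cluster -> flag -> classify)
    otu_tables: dict[str, otu_mod.OtuTable] = {}
    spurious_tables: dict[str, pd.DataFrame] = {}
    bias_reports: dict[str, stats.BiasReport] = {}
    rar_rng = np.random.default_rng(config.seed + 17)
    for comm in config.communities:
        lib_ids = [l for l in bundle.libraries if l.startswith(comm + ".")]
        lib_seqs: dict[str, list[str]] = {}
        for lib_id in lib_ids:
            fwd = _to_read_records(bundle.libraries[lib_id].fwd, "fwd")
            rev = _to_read_records(bundle.libraries[lib_id].rev, "rev")
            merged, _ = qc.process_pairs(fwd, rev, level=config.otu_trim_level,
                                         min_len=config.otu_min_len, library_id=lib_id)
            lib_seqs[lib_id] = [r.seq for r in merged]
        depth = config.rarefaction_depth or min(len(v) for v in lib_seqs.values())
        depth = min(depth, min(len(v) for v in lib_seqs.values()))
        lib_seqs = {lib: otu_mod.rarefy(seqs, depth, rng=rar_rng, library=lib)
                    for lib, seqs in lib_seqs.items()}
        table = otu_mod.build_otu_table(lib_seqs)
        table = otu_mod.flag_unique_otus(table, {lib: lib for lib in lib_seqs})
        table = otu_mod.classify_artifacts(table, mock_refs, db_refs, mode=mode)
        otu_tables[comm] = table
        spurious_tables[comm] = otu_mod.spurious_summary(table)
        bias_reports[comm] = stats.bias_report(table, bundle.designs[comm])
        log.info("community %s: %d OTUs at depth %d", comm, len(table.otu_ids), depth)

    # --- truth-vs-call confusion (read level, chimera calls)
    conf_rows = []
    for lib_id, merged in merged_raw.items():
        for r in merged:
            t = truth_by_read[r.read_id]
            conf_rows.append({"library": lib_id, "origin": t.origin})
    confusion = (pd.DataFrame(conf_rows).groupby(["library", "origin"]).size()
                 .unstack(fill_value=0)) if conf_rows else None

    result = EvaluationBundle(chimera_table, error_table, otu_tables,
                              spurious_tables, bias_reports, confusion)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(chimera_table, outdir / "chimera_accounting.tsv",
                  header_comment=header, index=False)
        write_tsv(error_table, outdir / "error_grid.tsv", header_comment=header, index=False)
        for comm, table in otu_tables.items():
            write_tsv(table.counts, outdir / f"otu_counts_{comm}.tsv", header_comment=header)
            cls = pd.DataFrame({"otu_id": table.otu_ids,
                                "classification": [table.classification.get(o, "")
                                                   for o in table.otu_ids],
                                "flag": [table.flags.get(o, "") for o in table.otu_ids]})
            write_tsv(cls, outdir / f"otu_classification_{comm}.tsv",
                      header_comment=header, index=False)
            write_tsv(spurious_tables[comm], outdir / f"spurious_summary_{comm}.tsv",
                      header_comment=header)
            rep = bias_reports[comm]
            write_tsv(rep.per_strain, outdir / f"bias_per_strain_{comm}.tsv",
                      header_comment=header)
            write_tsv(rep.per_cluster, outdir / f"bias_per_cluster_{comm}.tsv",
                      header_comment=header)
            write_tsv(rep.pearson_per_library, outdir / f"pearson_{comm}.tsv",
                      header_comment=header)
        if confusion is not None:
            write_tsv(confusion, outdir / "truth_confusion.tsv", header_comment=header)
    return result
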