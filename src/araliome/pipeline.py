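"""End-to-end orchestration: ingest -> matrices -> trees -> discordance ->
substitution spectra -> dS/dN -> report.

A run is driven by one :class:`RunConfig` (YAML-loadable), executes stages
in dependency order, writes plain-text artifacts under the output
directory, and records a manifest with a config fingerprint.  Re-running a
completed pipeline with an unchanged config skips all recomputation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import dnds as dnds_mod
from . import mutspec as mutspec_mod
from . import trees as trees_mod
from .align import Alignment
from .matrices import (SuperMatrix, align_gene, build_supermatrix,
                       extract_pos12, load_prealigned_fasta, read_fasta,
                       translate_matrix, write_fasta, write_nexus)
from .plastome import DEFAULT_EXCLUDE, extract_cds, read_genbank


class ConfigError(ValueError):
    """Invalid run configuration (raised before any work)."""


class StageError(RuntimeError):
    """A pipeline stage failed; completed artifacts are left in place."""


@dataclass
class RunConfig:
    """Study design for one pipeline run.

    Inputs are either a directory of GenBank plastomes (``genbank_dir``) or
    a directory of per-gene FASTA files (``genes_dir``); set
    ``genes_prealigned`` when the per-gene files are already aligned (e.g.
    simulator output).  ``grouping`` assigns every non-reference taxon to a
    group; ``clades`` names tip sets for the discordance table.
    """

    outdir: str
    reference: str
    genbank_dir: str | None = None
    genes_dir: str | None = None
    genes_prealigned: bool = False
    whole_alignment: str | None = None  # external-aligner hook
    external_trees: dict[str, str] = field(default_factory=dict)
    exclude: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDE))
    matrix_kinds: tuple[str, ...] = ("cds", "pos12", "protein")
    grouping: dict[str, str] = field(default_factory=dict)
    clades: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tree_model: str = "k2p"
    bootstrap: int = 100
    dnds_methods: tuple[str, ...] = ("ng86",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude", "matrix_kinds", "dnds_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "clades" in raw:
            raw["clades"] = {k: tuple(v) for k, v in raw["clades"].items()}
        return cls(**raw)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not (self.genbank_dir or self.genes_dir):
            raise ConfigError("one of genbank_dir or genes_dir is required")
        for kind in self.matrix_kinds:
            if kind not in ("cds", "pos12", "protein", "whole"):
                raise ConfigError(f"unknown matrix kind {kind!r}")
        if "whole" in self.matrix_kinds and not (
                self.whole_alignment or "whole" in self.external_trees):
            raise ConfigError("matrix kind 'whole' needs whole_alignment or "
                              "an external tree (external aligner hook)")


@dataclass
class RunReport:
    """Artifact manifest plus the summary tables of one run."""

    manifest: dict[str, list[str]]
    fingerprint: str
    table1: pd.DataFrame | None
    discordance: trees_mod.DiscordanceReport | None
    spectrum_table: pd.DataFrame | None
    dnds_tables: dict[str, pd.DataFrame]
    group_stats: dict[str, dnds_mod.GroupComparison]


def _log(fh, **kv) -> None:
    line = " ".join(f"{k}={v}" for k, v in kv.items())
    fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {line}\n")
    fh.flush()


def _ingest(cfg: RunConfig, outdir: Path, log) -> dict[str, dict[str, str]]:
    """Per-gene CDS collections: gene -> taxon -> sequence."""
    genes: dict[str, dict[str, str]] = {}
    if cfg.genbank_dir:
        paths = sorted(Path(cfg.genbank_dir).glob("*.gb")) + \
            sorted(Path(cfg.genbank_dir).glob("*.gbk"))
        if not paths:
            raise StageError(f"ingest: no GenBank files in {cfg.genbank_dir}")
        for path in paths:
            for record in read_genbank(path):
                cds = extract_cds(record, exclude=set(cfg.exclude))
                for gene, seq in cds.items():
                    genes.setdefault(gene, {})[record.id] = seq
        _log(log, stage="ingest", records="genbank", n_genes=len(genes))
    else:
        paths = sorted(Path(cfg.genes_dir).glob("*.fasta")) + \
            sorted(Path(cfg.genes_dir).glob("*.fa"))
        if not paths:
            raise StageError(f"ingest: no FASTA files in {cfg.genes_dir}")
        for path in paths:
            genes[path.stem] = read_fasta(path)
        _log(log, stage="ingest", records="fasta", n_genes=len(genes))
    taxa = sorted({t for g in genes.values() for t in g})
    if cfg.reference not in taxa:
        raise ConfigError(
            f"reference taxon {cfg.reference!r} absent from inputs")
    missing = [t for t in taxa
               if t != cfg.reference and cfg.grouping
               and t not in cfg.grouping]
    if missing:
        raise ConfigError(f"grouping does not cover taxa: {missing}")
    gdir = outdir / "genes"
    gdir.mkdir(exist_ok=True)
    for gene, seqs in genes.items():
        write_fasta(seqs, gdir / f"{gene}.fasta")
    return genes


def _build_matrices(cfg: RunConfig, genes: Mapping[str, Mapping[str, str]],
                    outdir: Path, log) -> dict[str, SuperMatrix]:
    taxa = sorted({t for g in genes.values() for t in g})
    per_gene: dict[str, Alignment] = {}
    for gene in sorted(genes):
        seqs = genes[gene]
        if cfg.genes_prealigned:
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) != 1:
                raise StageError(
                    f"matrices: gene {gene} marked prealigned but rows "
                    f"differ in length")
            per_gene[gene] = Alignment(kind="codon",
                                       rows=sorted(seqs.items()))
        else:
            per_gene[gene] = align_gene(seqs)
    sm_cds = build_supermatrix(per_gene, taxa)
    matrices: dict[str, SuperMatrix] = {}
    if "cds" in cfg.matrix_kinds:
        matrices["cds"] = sm_cds
    if "pos12" in cfg.matrix_kinds:
        matrices["pos12"] = extract_pos12(sm_cds)
    if "protein" in cfg.matrix_kinds:
        matrices["protein"] = translate_matrix(sm_cds)
    if "whole" in cfg.matrix_kinds and cfg.whole_alignment:
        matrices["whole"] = load_prealigned_fasta(cfg.whole_alignment)
    matrices.setdefault("cds", sm_cds)
    mdir = outdir / "matrices"
    mdir.mkdir(exist_ok=True)
    for kind, sm in matrices.items():
        write_fasta(sm.alignment, mdir / f"{kind}.fasta")
        write_nexus(sm, mdir / f"{kind}.nex")
        _log(log, stage="matrices", kind=kind, n_cols=sm.n_cols,
             n_taxa=len(sm.taxa))
    return matrices


def _build_trees(cfg: RunConfig, matrices: Mapping[str, SuperMatrix],
                 outdir: Path, log):
    tdir = outdir / "trees"
    tdir.mkdir(exist_ok=True)
    trees = {}
    for kind in cfg.matrix_kinds:
        if kind in cfg.external_trees:
            trees[kind] = trees_mod.read_newick(cfg.external_trees[kind])
            _log(log, stage="trees", kind=kind, source="external")
        elif kind in matrices:
            aln = matrices[kind].alignment
            model = "p" if aln.kind == "protein" else cfg.tree_model
            trees[kind] = trees_mod.bootstrap_support(
                aln, B=cfg.bootstrap, model=model, seed=cfg.seed)
            _log(log, stage="trees", kind=kind, source="nj",
                 model=model, bootstrap=cfg.bootstrap, seed=cfg.seed)
        else:
            continue
        trees_mod.write_newick(trees[kind], tdir / f"{kind}.nwk")
    return trees


def run(cfg: RunConfig) -> RunReport:
    """Execute the pipeline; idempotent for an unchanged config."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    fingerprint = cfg.fingerprint()
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("fingerprint") == fingerprint and all(
                Path(p).exists()
                for paths in old["artifacts"].values() for p in paths):
            return _load_report(cfg, outdir, old)
    log = open(outdir / "run.log", "w")
    manifest: dict[str, list[str]] = {}
    _log(log, stage="start", fingerprint=fingerprint, seed=cfg.seed)

    genes = _ingest(cfg, outdir, log)
    manifest["ingest"] = sorted(str(p) for p in (outdir / "genes").glob("*"))

    matrices = _build_matrices(cfg, genes, outdir, log)
    manifest["matrices"] = sorted(str(p)
                                  for p in (outdir / "matrices").glob("*"))

    trees = _build_trees(cfg, matrices, outdir, log)
    manifest["trees"] = sorted(str(p) for p in (outdir / "trees").glob("*"))

    discordance = None
    if len(trees) >= 2:
        discordance = trees_mod.clade_support_table(trees, cfg.clades)
        discordance.to_tsv(outdir / "discordance.tsv")
        manifest["discord"] = [str(outdir / "discordance.tsv")]

    cds_aln = matrices["cds"].alignment
    spectra = mutspec_mod.spectra_vs_reference(cds_aln, cfg.reference)
    spec_table = mutspec_mod.spectrum_table(spectra)
    spec_table.to_csv(outdir / "mutspec.tsv", sep="\t")
    manifest["mutspec"] = [str(outdir / "mutspec.tsv")]
    _log(log, stage="mutspec", n_queries=len(spectra))

    dnds_tables: dict[str, pd.DataFrame] = {}
    estimates_by_method = {}
    for method in cfg.dnds_methods:
        ests = dnds_mod.estimates_vs_reference(cds_aln.rows, cfg.reference,
                                               method=method)
        estimates_by_method[method] = ests
        table = pd.DataFrame([{
            "query": e.pair[0], "S": e.S, "N": e.N, "Sd": e.Sd, "Nd": e.Nd,
            "dS": e.dS, "dN": e.dN,
            "omega": float("nan") if e.omega is None else e.omega,
            "method": e.method, "codons_used": e.codons_used,
            "flags": ",".join(e.flags)} for e in ests]).set_index("query")
        table.to_csv(outdir / f"dnds_{method}.tsv", sep="\t")
        dnds_tables[method] = table
        manifest[f"dnds_{method}"] = [str(outdir / f"dnds_{method}.tsv")]
        _log(log, stage="dnds", method=method, n_pairs=len(ests))

    group_stats: dict[str, dnds_mod.GroupComparison] = {}
    table1 = None
    if cfg.grouping:
        summaries = mutspec_mod.summarize_groups(spectra, cfg.grouping)
        primary = cfg.dnds_methods[0]
        ds_vals = {e.pair[0]: e.dS for e in estimates_by_method[primary]}
        dn_vals = {e.pair[0]: e.dN for e in estimates_by_method[primary]}
        for metric, vals in (("dS", ds_vals), ("dN", dn_vals)):
            try:
                group_stats[metric] = dnds_mod.group_compare(
                    vals, cfg.grouping, metric=metric)
            except ValueError:
                pass
        table1 = render_table1(summaries, ds_vals, dn_vals, cfg.grouping)
        table1.to_csv(outdir / "table1.tsv", sep="\t")
        manifest["report"] = [str(outdir / "table1.tsv")]
    manifest_path.write_text(json.dumps(
        {"fingerprint": fingerprint, "artifacts": manifest}, indent=1))
    _log(log, stage="done")
    log.close()
    return RunReport(manifest=manifest, fingerprint=fingerprint,
                     table1=table1, discordance=discordance,
                     spectrum_table=spec_table, dnds_tables=dnds_tables,
                     group_stats=group_stats)


def _load_report(cfg: RunConfig, outdir: Path, manifest: dict) -> RunReport:
    spec_table = pd.read_csv(outdir / "mutspec.tsv", sep="\t",
                             index_col="query")
    dnds_tables = {m: pd.read_csv(outdir / f"dnds_{m}.tsv", sep="\t",
                                  index_col="query")
                   for m in cfg.dnds_methods}
    t1_path = outdir / "table1.tsv"
    table1 = pd.read_csv(t1_path, sep="\t", index_col=0) \
        if t1_path.exists() else None
    return RunReport(manifest=manifest["artifacts"],
                     fingerprint=manifest["fingerprint"], table1=table1,
                     discordance=None, spectrum_table=spec_table,
                     dnds_tables=dnds_tables, group_stats={})


def render_table1(summaries, ds_vals: Mapping[str, float],
                  dn_vals: Mapping[str, float],
                  grouping: Mapping[str, str]) -> pd.DataFrame:
    """Group-level summary table: dS, dN and the six substitution classes
    as ``mean ± sd`` strings, column maxima flagged with ``*``.

    Singleton groups are excluded (their names appear in the
    ``excluded_singletons`` attribute on the frame).
    """
    from .mutspec import CLASSES

    rows = {}
    numeric = {}
    excluded = []
    for summary in summaries:
        if summary.singleton:
            excluded.append(summary.group)
            continue
        ds = [ds_vals[m] for m in summary.members if m in ds_vals]
        dn = [dn_vals[m] for m in summary.members if m in dn_vals]
        entry_num = {}
        entry_num["dS"] = (float(pd.Series(ds).mean()),
                           float(pd.Series(ds).std(ddof=1)))
        entry_num["dN"] = (float(pd.Series(dn).mean()),
                           float(pd.Series(dn).std(ddof=1)))
        for cls in CLASSES:
            entry_num[cls] = (summary.mean[cls], summary.sd[cls])
        numeric[summary.group] = entry_num
    for group, entry in numeric.items():
        rows[group] = {col: f"{m:.4f} ± {s:.4f}" if col in ("dS", "dN")
                       else f"{m:.1f} ± {s:.1f}"
                       for col, (m, s) in entry.items()}
    frame = pd.DataFrame(rows).T
    if not frame.empty:
        for col in frame.columns:
            best = max(numeric, key=lambda g: numeric[g][col][0])
            frame.loc[best, col] = frame.loc[best, col] + " *"
    frame.attrs["excluded_singletons"] = excluded
    return frame
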