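"""One-command orchestration: simulate -> demux -> assemble -> otu -> classify.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
per-stage parameters; :func:`run_pipeline` executes the stages in order,
writes every intermediate under the output directory and records each
file's SHA-256 in ``manifest.tsv``, so a rerun with the same config is
checkable for bitwise reproducibility.  All randomness derives from one
global seed via stage-name-hashed child seeds.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import demux as demux_mod
from . import otu as otu_mod
from . import phylo as phylo_mod
from . import sim as sim_mod
from . import wimseex as wimseex_mod
from .seq_io import (Read, SampleSheetRow, read_fasta, read_fastq,
                     read_sample_sheet, write_fasta, write_fastq)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    ``profiles`` maps sample name -> {template_id: abundance}; ``n_reads``
    maps sample name -> pool size.  ``templates``/``references`` are FASTA
    paths or None to use the packaged synthetic reference set.
    """

    outdir: str
    seed: int
    sample_sheet: str | None = None
    templates: str | None = None
    references: str | None = None
    profiles: dict = field(default_factory=dict)
    n_reads: dict = field(default_factory=dict)
    error_model: dict = field(default_factory=dict)
    demux: dict = field(default_factory=dict)
    assembly: dict = field(default_factory=dict)
    otu_identity: float = otu_mod.DEFAULT_IDENTITY

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: stable under adding or reordering stages."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """All validation problems at once; an empty list means OK."""
    errors: list[str] = []
    for name in ("sample_sheet", "templates", "references"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    if cfg.profiles:
        if cfg.seed is None:
            errors.append("seed required when simulation is enabled")
        for sample, members in cfg.profiles.items():
            total = sum(members.values())
            if abs(total - 1.0) > 1e-9:
                errors.append(f"profile {sample!r}: abundances sum to {total}, not 1")
            if cfg.n_reads.get(sample, 0) < 1:
                errors.append(f"profile {sample!r}: n_reads missing or < 1")
    try:
        wimseex_mod.WimseexParams(**cfg.assembly)
    except (TypeError, ValueError) as exc:
        errors.append(f"assembly parameters: {exc}")
    try:
        sim_mod.ErrorModel(**cfg.error_model)
    except (TypeError, ValueError) as exc:
        errors.append(f"error model: {exc}")
    if not 0 < cfg.otu_identity <= 1:
        errors.append("otu_identity must be in (0, 1]")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_sample_sheet() -> list[SampleSheetRow]:
    """The four-species tag layout of the weevil survey: shared TCAG key,
    universal V1–V2 16S primer pair, species-specific 6 bp MIDs."""
    fwd, rev = "MGAGTTTGATCCTGGCTCAG", "GCTGCCTCCCGTAGGAGT"
    return [
        SampleSheetRow("O_salicicola", "TCAG", "ATCGCG", "CGCGAT", fwd, rev),
        SampleSheetRow("O_rugosostriatus", "TCAG", "ATAGCC", "GGCTAT", fwd, rev),
        SampleSheetRow("O_sulcatus", "TCAG", "CCATAG", "CTATGG", fwd, rev),
        SampleSheetRow("O_armadillo", "TCAG", "CTTGAG", "CTCAAG", fwd, rev),
    ]


#: Dominant-OTU fractions of the four weevil survey samples, used by the
#: bundled demo configuration.
DEMO_DOMINANCES = {
    "O_salicicola": 0.9083,
    "O_rugosostriatus": 0.9087,
    "O_sulcatus": 0.9916,
    "O_armadillo": 0.9349,
}

DEMO_N_READS = {
    "O_salicicola": 6073,
    "O_rugosostriatus": 8584,
    "O_sulcatus": 6412,
    "O_armadillo": 6311,
}


def demo_config(outdir, seed: int, scale: float = 1.0) -> PipelineConfig:
    """The bundled demo: four species-tagged pools over the packaged
    synthetic reference set, each dominated by one endosymbiont-like
    template with a tail of minor templates from other clades.

    ``scale`` shrinks the pool sizes proportionally for quick runs.
    """
    refs = sim_mod.synthetic_references()
    by_group: dict[str, list[str]] = {}
    for r in refs:
        by_group.setdefault(r["group"], []).append(r["accession"])
    rick, nard, neo, env = (by_group["Rickettsia-like"], by_group["Nardonella-like"],
                            by_group["Neoehrlichia-like"], by_group["environmental"])
    dominant = {
        "O_salicicola": nard[0],
        "O_rugosostriatus": rick[0],
        "O_sulcatus": rick[1],
        "O_armadillo": nard[1],
    }
    minors = {
        "O_salicicola": [neo[0], env[0]],
        "O_rugosostriatus": [neo[1], nard[2], env[1]],
        "O_sulcatus": [neo[2], env[0]],
        "O_armadillo": [neo[0], rick[2], env[1]],
    }
    profiles = {}
    for sample, dom_frac in DEMO_DOMINANCES.items():
        rest = 1.0 - dom_frac
        mem = {dominant[sample]: dom_frac}
        tail = minors[sample]
        # minor mass split 60/40 (or 50/30/20) across the tail templates
        weights = {2: [0.6, 0.4], 3: [0.5, 0.3, 0.2]}[len(tail)]
        for tid, w in zip(tail, weights):
            mem[tid] = rest * w
        profiles[sample] = mem
    n_reads = {s: max(50, int(round(n * scale))) for s, n in DEMO_N_READS.items()}
    return PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        profiles=profiles,
        n_reads=n_reads,
        assembly={"min_window_identity": 0.95, "max_bases": 10_000_000},
    )


def _load_templates(cfg: PipelineConfig) -> tuple[dict[str, str], list[phylo_mod.ReferenceRecord]]:
    if cfg.templates is None:
        recs = sim_mod.synthetic_references()
        templates = {r["accession"]: r["bases"] for r in recs}
        refrecs = [phylo_mod.ReferenceRecord(r["accession"], r["label"], r["bases"], r["group"])
                   for r in recs]
    else:
        reads = list(read_fasta(cfg.templates))
        templates = {r.id: r.bases for r in reads}
        refrecs = [phylo_mod.ReferenceRecord(r.id, r.id, r.bases) for r in reads]
    if cfg.references is not None:
        refrecs = [phylo_mod.ReferenceRecord(r.id, r.id, r.bases)
                   for r in read_fasta(cfg.references)]
    return templates, refrecs


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Writes: ``reads.fastq`` + ``truth.tsv`` (when simulating), per-sample
    demux pools + ``demux_summary.tsv``, ``contigs.fasta`` +
    ``contigs.tsv``, ``otus.fasta`` + ``otu_table.tsv``, and
    ``manifest.tsv`` with a SHA-256 per artefact.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str, str, str]] = []

    def record(stage: str, path: Path, params: dict) -> None:
        manifest.append((stage, path.name, _sha256(path), json.dumps(params, sort_keys=True)))

    sheet = (read_sample_sheet(cfg.sample_sheet) if cfg.sample_sheet
             else default_sample_sheet())
    rows = {r.sample: r for r in sheet}
    templates, refrecs = _load_templates(cfg)
    model = sim_mod.ErrorModel(**cfg.error_model)

    # --- simulate ---------------------------------------------------------
    if cfg.profiles:
        profs = [
            sim_mod.CommunityProfile(
                sample=s,
                members=sorted(cfg.profiles[s].items()),
                n_reads=int(cfg.n_reads[s]),
                tag=rows[s],
            )
            for s in cfg.profiles
        ]
        reads, truth = sim_mod.simulate(profs, templates, model,
                                        stage_seed(cfg.seed, "simulate"))
        write_fastq(reads, outdir / "reads.fastq")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        record("simulate", outdir / "reads.fastq",
               {"seed": stage_seed(cfg.seed, "simulate"), "model": asdict(model)})
        record("simulate", outdir / "truth.tsv", {})
    else:
        reads = list(read_fastq(outdir / "reads.fastq"))

    # --- demultiplex ------------------------------------------------------
    dmx_params = dict(cfg.demux)
    pools = demux_mod.demultiplex(reads, sheet, **dmx_params)
    for name, pool in pools.pools.items():
        path = outdir / f"{name}.fastq"
        write_fastq(pool, path)
        record("demux", path, dmx_params)
    pools.summary.to_csv(outdir / "demux_summary.tsv", sep="\t", index=False)
    record("demux", outdir / "demux_summary.tsv", dmx_params)

    # --- assemble ---------------------------------------------------------
    params = wimseex_mod.WimseexParams(**cfg.assembly)
    all_contigs: dict[str, list[wimseex_mod.Contig]] = {}
    contig_rows = []
    fasta_records = []
    for row in sheet:
        anchor = wimseex_mod.make_anchor(row, params.anchor_len_primer)
        contigs = wimseex_mod.assemble_tag(pools.pool(row.sample), anchor, params,
                                           sample=row.sample, tag=row)
        all_contigs[row.sample] = contigs
        for k, c in enumerate(contigs, start=1):
            cid = f"{row.sample}_contig{k:02d}"
            fasta_records.append(Read(f"{cid} support={c.support} sample={c.sample}",
                                      c.bases))
            contig_rows.append((row.sample, cid, c.support, len(c.bases)))
    write_fasta(fasta_records, outdir / "contigs.fasta")
    pd.DataFrame(contig_rows, columns=["sample", "contig_id", "support", "length"]
                 ).to_csv(outdir / "contigs.tsv", sep="\t", index=False)
    record("assemble", outdir / "contigs.fasta", asdict(params))
    record("assemble", outdir / "contigs.tsv", asdict(params))

    # --- otu + classify ---------------------------------------------------
    otus_by_sample: dict[str, list[otu_mod.ConsensusOTU]] = {}
    for row in sheet:
        contigs = all_contigs[row.sample]
        if not contigs:
            continue
        otus = otu_mod.contigs_to_otus(contigs, row, cfg.otu_identity)
        for o in otus:
            acc, ident = phylo_mod.best_hit(o.bases, refrecs)
            o.closest_match = f"{acc} ({ident:.4f})"
        otus_by_sample[row.sample] = otus
    table = otu_mod.build_table(otus_by_sample)
    table.to_csv(outdir / "otu_table.tsv", sep="\t", index=False)
    write_fasta([Read(o.otu_id, o.bases)
                 for otus in otus_by_sample.values() for o in otus],
                outdir / "otus.fasta")
    record("otu", outdir / "otu_table.tsv", {"identity": cfg.otu_identity})
    record("otu", outdir / "otus.fasta", {"identity": cfg.otu_identity})

    pd.DataFrame(manifest, columns=["stage", "file", "sha256", "params"]
                 ).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir
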