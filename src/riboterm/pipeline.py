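"""Pipeline orchestration: a single YAML config drives the stages
simulate -> tracks -> metagene / expression / rpor / recoding, with
deterministic provenance stamps (seed, config hash) in every output."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import metagene as mg
from . import recoding as rc
from . import rpor_stats as rp
from .annotation import compute_gaps, load_annotation, load_genome, \
    stop_codon_frequencies
from .expression import expression_table, quantify
from .simulate import (SimParams, simulate_genome, simulate_tracks,
                       write_fasta, write_gff3, write_truth)
from .tracks import DensityTrack, normalize_per_million, read_wiggle, \
    write_wiggle

log = logging.getLogger(__name__)


@dataclass
class MetageneConfig:
    min_window_counts: float = 1.0
    min_downstream_gap: int = 50
    count_filter: bool = True
    gap_filter: bool = True


@dataclass
class ExpressionConfig:
    mask_codons: int = 5
    min_counts: float = 100.0


@dataclass
class RporConfig:
    min_gap: int = 65
    min_density: float = 0.1
    drop_zeros: bool = True


@dataclass
class RecodingConfig:
    drop_threshold: float = 0.3
    min_pre_density: float = 0.2
    min_region_counts: float = 10.0


@dataclass
class PathsConfig:
    genome: str | None = None
    annotation: str | None = None
    fp_plus: str | None = None
    fp_minus: str | None = None
    mrna_plus: str | None = None
    mrna_minus: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "riboterm-out"
    simulate: dict | None = None   # SimParams overrides; None = load from paths
    paths: PathsConfig = field(default_factory=PathsConfig)
    metagene: MetageneConfig = field(default_factory=MetageneConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    rpor: RporConfig = field(default_factory=RporConfig)
    recoding: RecodingConfig = field(default_factory=RecodingConfig)


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    sections = {"metagene": MetageneConfig, "expression": ExpressionConfig,
                "rpor": RporConfig, "recoding": RecodingConfig,
                "paths": PathsConfig}
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in sections:
            kwargs[key] = _build_section(sections[key], value or {}, key)
        elif key == "simulate":
            if value is not None:
                allowed = {f.name for f in dataclasses.fields(SimParams)}
                bad = set(value) - allowed
                if bad:
                    raise ValueError(f"unknown keys in config section "
                                     f"'simulate': {sorted(bad)}")
            kwargs[key] = value
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded,
    so identical analyses into different directories share a stamp)."""
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(path: str, df: pd.DataFrame, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(stamp)
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_track_pair(plus: str, minus: str, chrom_lengths: dict[str, int]
                    ) -> DensityTrack:
    track = DensityTrack(chrom_lengths)
    read_wiggle(plus, "+", chrom_lengths, into=track)
    read_wiggle(minus, "-", chrom_lengths, into=track)
    return track


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns a result bundle.

    Re-running with an identical config reproduces byte-identical outputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stamp = f"# riboterm seed={config.seed} config={config_hash(config)}\n"

    if config.simulate is not None:
        params = SimParams(**{**config.simulate, "seed": config.seed})
        genome, orfs, truth = simulate_genome(params)
        chrom_lengths = {c: g.length for c, g in genome.items()}
        fp_raw, mrna_raw = simulate_tracks(orfs, truth, params,
                                           chrom_lengths=chrom_lengths)
        write_fasta(genome, os.path.join(config.out_dir, "genome.fa"))
        write_gff3(orfs, os.path.join(config.out_dir, "annotation.gff3"))
        write_truth(truth, os.path.join(config.out_dir, "truth.tsv"))
        for name, track in (("fp", fp_raw), ("mrna", mrna_raw)):
            for strand, tag in (("+", "plus"), ("-", "minus")):
                write_wiggle(track, strand,
                             os.path.join(config.out_dir, f"{name}_{tag}.wig"))
    else:
        p = config.paths
        for needed in ("genome", "annotation", "fp_plus", "fp_minus",
                       "mrna_plus", "mrna_minus"):
            value = getattr(p, needed)
            if value is None or not os.path.exists(value):
                raise FileNotFoundError(f"missing input {needed!r}: {value}")
        genome = load_genome(p.genome)
        orfs = load_annotation(genome, p.annotation)
        chrom_lengths = {c: g.length for c, g in genome.items()}
        orfs = compute_gaps(orfs, chrom_lengths)
        fp_raw = load_track_pair(p.fp_plus, p.fp_minus, chrom_lengths)
        mrna_raw = load_track_pair(p.mrna_plus, p.mrna_minus, chrom_lengths)

    fp = normalize_per_million(fp_raw) if fp_raw.units == "raw" else fp_raw
    mrna = normalize_per_million(mrna_raw) if mrna_raw.units == "raw" else mrna_raw

    results: dict = {"orfs": orfs, "fp": fp, "mrna": mrna}

    # metagene: global + per-stop-codon strata
    m = config.metagene
    profiles = []
    for stratum, genes in [("all", orfs)] + \
            [(s, g) for s, g in mg.stratify(orfs).items() if len(s) == 3 and g]:
        try:
            profiles.append(mg.metagene_profile(
                genes, fp, min_window_counts=m.min_window_counts,
                min_downstream_gap=m.min_downstream_gap,
                count_filter=m.count_filter, gap_filter=m.gap_filter,
                stratum=stratum))
        except ValueError as err:
            log.warning("metagene stratum %s skipped: %s", stratum, err)
    results["metagene"] = profiles
    _stamp(os.path.join(config.out_dir, "metagene.tsv"),
           pd.concat([p.to_frame() for p in profiles], ignore_index=True), stamp)

    # expression
    e = config.expression
    expr = quantify(orfs, fp, mrna, mask_codons=e.mask_codons,
                    min_counts=e.min_counts)
    results["expression"] = expr
    _stamp(os.path.join(config.out_dir, "expression.tsv"),
           expression_table(expr), stamp)

    # rpor
    r = config.rpor
    elig = rp.eligible_genes(orfs, fp, mrna, min_gap=r.min_gap,
                             min_density=r.min_density)
    records = rp.rpor_table(elig, fp)
    results["rpor"] = records
    _stamp(os.path.join(config.out_dir, "rpor.tsv"),
           pd.DataFrame([vars(x) for x in records],
                        columns=["gene_id", "orf_mean", "post_mean", "rpor"]),
           stamp)

    # recoding
    c = config.recoding
    calls = rc.classify_genes(elig, genome, fp,
                              drop_threshold=c.drop_threshold,
                              min_pre_density=c.min_pre_density,
                              min_region_counts=c.min_region_counts)
    results["recoding"] = calls
    _stamp(os.path.join(config.out_dir, "recoding.tsv"),
           rc.calls_table(calls), stamp)
    called = [x for x in calls if x.label in ("likely", "possible")]
    if called:
        enr = rc.enrichment_chi2([next(o.stop_codon for o in orfs
                                       if o.gene_id == x.gene_id)
                                  for x in called],
                                 stop_codon_frequencies(orfs))
        results["enrichment"] = enr
        with open(os.path.join(config.out_dir, "enrichment.json"), "w") as fh:
            json.dump({"observed": enr.observed, "expected": enr.expected,
                       "chi2": enr.chi2, "df": enr.df, "p_value": enr.p_value,
                       "stamp": stamp.strip("# \n")}, fh, indent=2, sort_keys=True)
    return results
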