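"""End-to-end orchestration of the co-evolution analysis.

``run_pipeline`` takes a validated :class:`RunConfig` and executes:
best-hit matrix construction (or loading) -> NPP normalization -> two
clade-scoped rankings -> top-k candidate sets -> overlap statistics ->
co-evolution edges on the union -> karyotype-band enrichment -> directional
drug filtering with tiering and the by-chance druggability expectation.
Every artifact is written as deterministic TSV/JSON, so re-running with the
same config and inputs is byte-identical.

One mandatory seed drives all stochastic stages through documented
sub-seeding (the seed XOR a CRC-32 hash of the stage name, reduced mod 2^31)
so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .drugs import druggable_frame, filter_druggable, tier_candidates
from .enrichment import (band_enrichment, band_results_frame,
                         candidates_without_band, chance_expectation,
                         combine_sets)
from .errors import PipelineError, ValidationError
from .io_formats import (DEFAULT_DIRECTIONAL_TYPES, read_blast_tab,
                         read_drug_table, read_gene_table,
                         read_species_table, write_table)
from .normalize import NormalizationConfig, npp
from .profile_matrix import DEFAULT_BIT_MIN, RawScoreMatrix, best_hits, matrix_summary
from .ranking import build_edges, rank_by_coevolution, top_k


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: (seed XOR crc32(stage)) mod 2^31."""
    return (seed ^ zlib.crc32(stage.encode("utf-8"))) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a full run needs; ``seed`` is mandatory, no silent default."""

    species_table: Path
    gene_table: Path
    drug_table: Path
    query: str
    seed: int
    out_dir: Path
    blast_dir: Path | None = None
    raw_matrix: Path | None = None
    clades: tuple[str, str] = ("all", "Mammalia")
    k: int = 200
    bit_min: float = DEFAULT_BIT_MIN
    edge_r_min: float = 0.7
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    B: int = 100_000
    allowed_drug_types: frozenset[str] = DEFAULT_DIRECTIONAL_TYPES
    enriched_band_q: float = 0.05  # bands with q <= this flag tier-2 candidates

    def validate(self) -> None:
        missing = [str(p) for p in (self.species_table, self.gene_table, self.drug_table)
                   if not Path(p).exists()]
        if (self.blast_dir is None) == (self.raw_matrix is None):
            raise ValidationError("exactly one of blast_dir / raw_matrix must be set")
        source = self.blast_dir if self.blast_dir is not None else self.raw_matrix
        if not Path(source).exists():
            missing.append(str(source))
        if missing:
            raise ValidationError(f"missing input file(s): {missing}")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        norm = raw.pop("normalization", None)
        kwargs = dict(raw)
        for key in ("species_table", "gene_table", "drug_table",
                    "blast_dir", "raw_matrix", "out_dir"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "clades" in kwargs:
            kwargs["clades"] = tuple(kwargs["clades"])
        if "allowed_drug_types" in kwargs:
            kwargs["allowed_drug_types"] = frozenset(kwargs["allowed_drug_types"])
        if norm:
            kwargs["normalization"] = NormalizationConfig(**norm)
        return cls(**kwargs)

    def echo(self) -> dict:
        return {
            "species_table": str(self.species_table),
            "gene_table": str(self.gene_table),
            "drug_table": str(self.drug_table),
            "blast_dir": str(self.blast_dir) if self.blast_dir else None,
            "raw_matrix": str(self.raw_matrix) if self.raw_matrix else None,
            "query": self.query,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "clades": list(self.clades),
            "k": self.k,
            "bit_min": self.bit_min,
            "edge_r_min": self.edge_r_min,
            "B": self.B,
            "normalization": {
                "method": self.normalization.method,
                "include_zeros": self.normalization.include_zeros,
                "drop_degenerate_species": self.normalization.drop_degenerate_species,
                "log_transform": self.normalization.log_transform,
            },
            "allowed_drug_types": sorted(self.allowed_drug_types),
            "enriched_band_q": self.enriched_band_q,
        }


def _run_stage(out_dir: Path, name: str, fn):
    try:
        return fn()
    except Exception as exc:
        # mark the run as failed so partial artifacts are not mistaken for results
        try:
            (out_dir / "FAILED").write_text(f"{name}: {exc}\n")
        except OSError:
            pass
        raise PipelineError(name, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    report: dict = {"version": __version__, "config": config.echo(),
                    "warnings": {}, "stage_seeds": {}}

    def load():
        species = read_species_table(config.species_table)
        genes = read_gene_table(config.gene_table)
        drug_df, dropped = read_drug_table(config.drug_table, config.allowed_drug_types)
        report["warnings"]["drug_rows_dropped"] = dropped
        return species, genes, drug_df

    species, genes, drug_df = _run_stage(out, "load", load)

    def build_matrix():
        if config.raw_matrix is not None:
            from .profile_matrix import apply_threshold
            m = RawScoreMatrix.from_tsv(config.raw_matrix, bit_min=0.0)
            return apply_threshold(m, config.bit_min)
        hits = []
        for f in sorted(Path(config.blast_dir).glob("*.tsv")):
            hits.extend(read_blast_tab(f))
        m = best_hits(hits, genes, species, bit_min=config.bit_min)
        m.to_tsv(out / "raw_matrix.tsv")
        return m

    matrix = _run_stage(out, "matrix", build_matrix)
    report["matrix"] = matrix_summary(matrix)
    del report["matrix"]["per_species_nonzero"]  # keep the report compact

    def normalize_stage():
        result = npp(matrix, genes, config.normalization)
        result.to_tsv(out / "npp.tsv")
        return result

    npp_matrix = _run_stage(out, "normalize", normalize_stage)
    report["dropped_species"] = npp_matrix.dropped_species

    def rank_stage():
        sets = {}
        rankings = {}
        for clade in config.clades:
            ranking = rank_by_coevolution(npp_matrix, config.query,
                                          species=species, clade=clade)
            label = f"{clade}-top{config.k}"
            cand = top_k(ranking, config.k, label=label)
            write_table(ranking.records, out / f"ranking_{clade}.tsv")
            write_table(pd.DataFrame({"gene_id": list(cand.genes)}),
                        out / f"candidates_{clade}.tsv")
            rankings[clade] = ranking
            sets[clade] = cand
        return rankings, sets

    rankings, sets = _run_stage(out, "rank", rank_stage)
    report["candidate_sets"] = {
        clade: {"k": s.k, "r_min_observed": s.r_min_observed,
                "n_species_used": rankings[clade].n_species_used}
        for clade, s in sets.items()
    }

    def overlap_stage():
        a, b = (sets[c] for c in config.clades)
        inter, union, result = combine_sets(a, b, N=len(genes))
        payload = {"k1": result.k1, "k2": result.k2, "N": result.N,
                   "observed": result.observed, "expected": result.expected,
                   "p_upper": result.p_upper, "union_size": result.union_size,
                   "intersection": inter}
        (out / "overlap.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
        return inter, union, result

    inter, union, overlap = _run_stage(out, "overlap", overlap_stage)
    report["overlap"] = {"observed": overlap.observed, "expected": overlap.expected,
                         "p_upper": overlap.p_upper, "union_size": overlap.union_size}

    def edges_stage():
        edges = build_edges(union, npp_matrix, species=species, clade="all",
                            r_min=config.edge_r_min)
        write_table(pd.DataFrame(
            [{"gene_a": e.gene_a, "gene_b": e.gene_b, "r": e.r} for e in edges],
            columns=["gene_a", "gene_b", "r"]),
            out / "edges.tsv")
        return edges

    edges = _run_stage(out, "edges", edges_stage)
    report["n_edges"] = len(edges)

    def bands_stage():
        seed = stage_seed(config.seed, "bands")
        report["stage_seeds"]["bands"] = seed
        report["warnings"]["candidates_without_band"] = len(
            candidates_without_band(union, genes))
        results = band_enrichment(union, genes, B=config.B, seed=seed)
        write_table(band_results_frame(results), out / "bands.tsv")
        return results

    bands = _run_stage(out, "bands", bands_stage)
    top_band = bands[0]
    report["top_band"] = {"band": top_band.band, "observed": top_band.observed,
                          "p_emp": top_band.p_emp, "q": top_band.q,
                          "fold": top_band.fold}

    def drugs_stage():
        druggable = filter_druggable(union, drug_df, config.allowed_drug_types)
        enriched = [b.band for b in bands if b.q <= config.enriched_band_q]
        tiered = tier_candidates(druggable, sets[config.clades[0]],
                                 sets[config.clades[1]], enriched, genes)
        write_table(druggable_frame(tiered), out / "druggable.tsv")
        seed = stage_seed(config.seed, "chance")
        report["stage_seeds"]["chance"] = seed
        positives = sorted(set(drug_df["gene_id"]) & set(genes["gene_id"]))
        chance = chance_expectation(len(union), positives, genes,
                                    B=config.B, seed=seed)
        return tiered, enriched, chance

    tiered, enriched, chance = _run_stage(out, "drugs", drugs_stage)
    report["druggable"] = {
        "observed": len(tiered),
        "tier1_genes": [c.gene_id for c in tiered if c.tier == 1],
        "enriched_bands": enriched,
        "chance_mean": chance.mean,
        "chance_sd": chance.sd,
    }

    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return report
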