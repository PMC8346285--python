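"""Synthetic species panels and clade-structured gene-loss score data.

The generator emulates the statistical structure phylogenetic profiling
relies on: genes belonging to the same functional module are lost together
in a species, retained homologs score in proportion to protein length with
an exponential decay in evolutionary distance from the reference species,
and lost genes still produce weak background-homology scores.

Generative model, per gene ``g`` with protein length ``L(g)`` and species
``s`` at distance ``d_s``:

* module loss indicator ``loss(j, s) ~ Bernoulli(p_loss)`` shared by every
  gene of module ``j`` (background genes draw independent indicators);
* retained: ``bits(g, s) = L(g) * beta * exp(-lam * d_s) * max(0, 1 + eps)``
  with ``eps ~ Normal(0, sigma)``;
* lost: ``bits(g, s) ~ Exponential(mean mu_bg)``.

Scores come back unthresholded (``bit_min = 0``); apply the standard
minimal-homology threshold with :func:`coevonet.profile_matrix.apply_threshold`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profile_matrix import RawScoreMatrix

#: clade -> (species count, min distance, max distance).  Distances are in
#: arbitrary evolutionary-distance units from the reference species; ranges
#: are ordered so closer clades (Mammalia) sit nearer the reference.
DEFAULT_CLADE_PLAN: dict[str, tuple[int, float, float]] = {
    "Mammalia": (20, 0.05, 0.45),
    "Vertebrata": (12, 0.5, 0.9),
    "Metazoa": (10, 0.9, 1.4),
    "Fungi": (10, 1.4, 2.0),
    "Protista": (8, 1.8, 2.6),
}

#: Synthetic karyotype bands: 10 chromosomes x 2 arms x 2 bands = 40 labels.
DEFAULT_BANDS: tuple[str, ...] = tuple(
    f"{chrom}{arm}{idx}" for chrom in range(1, 11) for arm in "pq" for idx in (11, 12)
)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generative model; the defaults define the standard test panel."""

    n_genes: int = 1000
    clade_plan: Mapping[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_PLAN)
    )
    module_sizes: Sequence[int] = (8,) * 10
    p_loss: float = 0.35          # probability a module is lost in a species
    beta: float = 2.0             # bits per residue for a retained homolog at distance 0
    lam: float = 0.5              # distance-decay rate, per distance unit
    sigma: float = 0.1            # multiplicative noise sd on retained scores
    mu_bg: float = 5.0            # mean background bit score for lost genes
    length_range: tuple[int, int] = (100, 800)
    seed: int = 0
    clade_block_loss: bool = False  # one loss draw per (module, clade) instead of per species
    band_list: Sequence[str] = DEFAULT_BANDS

    def __post_init__(self):
        if not (0.0 <= self.p_loss <= 1.0):
            raise ValidationError(f"p_loss must be in [0,1], got {self.p_loss}")
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.mu_bg < 0:
            raise ValidationError("mu_bg must be >= 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid length_range {self.length_range}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: module memberships and loss indicators.

    ``loss`` is modules x species (shared within a module), ``background_loss``
    is background genes x species (independent per gene).
    """

    module_of: dict[str, int | None]
    loss: pd.DataFrame
    background_loss: pd.DataFrame
    params: SimulationParams

    def module_members(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_of.items() if m == module)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of": {g: (m if m is not None else "background")
                          for g, m in sorted(self.module_of.items())},
            "loss": {str(j): self.loss.loc[j].astype(int).to_dict()
                     for j in self.loss.index},
            "background_loss": {g: self.background_loss.loc[g].astype(int).to_dict()
                                for g in self.background_loss.index},
            "params": {
                "n_genes": self.params.n_genes,
                "module_sizes": list(self.params.module_sizes),
                "p_loss": self.params.p_loss,
                "beta": self.params.beta,
                "lam": self.params.lam,
                "sigma": self.params.sigma,
                "mu_bg": self.params.mu_bg,
                "length_range": list(self.params.length_range),
                "seed": self.params.seed,
                "clade_block_loss": self.params.clade_block_loss,
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def gene_ids(n_genes: int) -> list[str]:
    """Deterministic zero-padded gene identifiers g0001, g0002, ..."""
    width = len(str(n_genes))
    return [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]


def simulate_species_panel(
    clade_plan: Mapping[str, tuple[int, float, float]],
    seed: int,
) -> pd.DataFrame:
    """Draw a species panel: ids sp1..spN in plan order, distances uniform per clade."""
    if not clade_plan:
        raise ValidationError("clade_plan must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for clade, (count, d_min, d_max) in clade_plan.items():
        if count < 1:
            raise ValidationError(f"clade {clade!r} has count {count} < 1")
        if d_min < 0 or d_max < d_min:
            raise ValidationError(f"clade {clade!r} has invalid range ({d_min}, {d_max})")
        dists = rng.uniform(d_min, d_max, size=count)
        for d in dists:
            counter += 1
            rows.append({"species_id": f"sp{counter}", "clade": clade,
                         "phylo_distance": float(d)})
    return pd.DataFrame(rows, columns=["species_id", "clade", "phylo_distance"])


def assign_modules(
    n_genes: int,
    module_sizes: Sequence[int],
    seed: int = 0,
) -> dict[str, int | None]:
    """Assign the first genes (in id order) to modules of the stated sizes.

    Remaining genes are background (``None``).  ``seed`` is reserved for a
    future shuffling option and currently unused.
    """
    if sum(module_sizes) > n_genes:
        raise ValidationError(
            f"module sizes sum to {sum(module_sizes)} > n_genes {n_genes}"
        )
    ids = gene_ids(n_genes)
    module_of: dict[str, int | None] = {}
    cursor = 0
    for j, size in enumerate(module_sizes):
        for g in ids[cursor:cursor + size]:
            module_of[g] = j
        cursor += size
    for g in ids[cursor:]:
        module_of[g] = None
    return module_of


def simulate_scores(
    params: SimulationParams,
) -> tuple[RawScoreMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate (unthresholded scores, gene table, planted truth) for one panel.

    Fully reproducible from ``params.seed``: the species panel is drawn from
    the seed itself and all remaining randomness from the child stream
    ``[seed, 1]``.
    """
    panel = simulate_species_panel(params.clade_plan, params.seed)
    rng = np.random.default_rng([params.seed, 1])

    genes = gene_ids(params.n_genes)
    n_species = len(panel)
    d = panel["phylo_distance"].to_numpy()
    clades = panel["clade"].to_numpy()

    lo, hi = params.length_range
    lengths = rng.integers(lo, hi + 1, size=params.n_genes)

    module_of = assign_modules(params.n_genes, params.module_sizes)
    n_modules = len(params.module_sizes)
    module_genes = [g for g in genes if module_of[g] is not None]
    bg_genes = [g for g in genes if module_of[g] is None]

    if params.clade_block_loss:
        clade_labels = list(dict.fromkeys(clades))
        per_clade = rng.random((n_modules, len(clade_labels))) < params.p_loss
        clade_idx = np.array([clade_labels.index(c) for c in clades])
        module_loss = per_clade[:, clade_idx]
    else:
        module_loss = rng.random((n_modules, n_species)) < params.p_loss
    bg_loss = rng.random((len(bg_genes), n_species)) < params.p_loss

    loss = np.zeros((params.n_genes, n_species), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in module_genes:
        loss[gene_pos[g]] = module_loss[module_of[g]]
    for i, g in enumerate(bg_genes):
        loss[gene_pos[g]] = bg_loss[i]

    eps = rng.normal(0.0, params.sigma, size=(params.n_genes, n_species)) \
        if params.sigma > 0 else np.zeros((params.n_genes, n_species))
    background = rng.exponential(params.mu_bg, size=(params.n_genes, n_species)) \
        if params.mu_bg > 0 else np.zeros((params.n_genes, n_species))

    retained = (
        lengths[:, None].astype(float)
        * params.beta
        * np.exp(-params.lam * d)[None, :]
        * np.maximum(0.0, 1.0 + eps)
    )
    values = np.where(loss, background, retained)

    bands = rng.choice(np.asarray(params.band_list, dtype=object), size=params.n_genes)
    gene_table = pd.DataFrame({
        "gene_id": genes,
        "symbol": [g.upper() for g in genes],
        "protein_length": lengths.astype(int),
        "chromosome": [_chromosome_of(b) for b in bands],
        "band": bands,
    })

    matrix = RawScoreMatrix(
        values=pd.DataFrame(values, index=genes, columns=panel["species_id"]),
        bit_min=0.0,
    )
    truth = SyntheticTruth(
        module_of=module_of,
        loss=pd.DataFrame(module_loss, index=range(n_modules),
                          columns=panel["species_id"]),
        background_loss=pd.DataFrame(bg_loss, index=bg_genes,
                                     columns=panel["species_id"]),
        params=params,
    )
    return matrix, gene_table, truth


def _chromosome_of(band: str) -> str:
    for i, ch in enumerate(band):
        if ch in "pq":
            return band[:i]
    return band


def simulate_drug_table(
    gene_table: pd.DataFrame,
    seed: int,
    frac_druggable: float = 0.1,
    p_nondirectional: float = 0.25,
) -> pd.DataFrame:
    """Synthetic drug–gene interaction table over a gene panel.

    Roughly ``frac_druggable`` of the genes get 1–3 interactions; a fraction
    of rows carry a non-directional type ("binder") to exercise vocabulary
    filtering.  Sources alternate between DGIdb-style and Open-Targets-style
    labels.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng([seed, 2])
    directional = sorted(
        ("inhibitor", "activator", "agonist", "antagonist", "blocker", "modulator")
    )
    rows = []
    drug_counter = 0
    for g in gene_table["gene_id"]:
        if rng.random() >= frac_druggable:
            continue
        for _ in range(int(rng.integers(1, 4))):
            drug_counter += 1
            if rng.random() < p_nondirectional:
                itype = "binder"
            else:
                itype = directional[int(rng.integers(len(directional)))]
            source = "DGIdb" if rng.random() < 0.5 else "OpenTargets"
            rows.append({"gene_id": g, "drug": f"drug{drug_counter:04d}",
                         "interaction_type": itype, "source": source})
    return pd.DataFrame(rows, columns=["gene_id", "drug", "interaction_type", "source"])
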