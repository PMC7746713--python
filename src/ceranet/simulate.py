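"""Self-contained synthetic ceRNA datasets with a planted sponge signal.

The generator emulates the statistical structure the pipeline assumes: heavy
tailed (log-normal) tissue expression with drop-outs, circRNA mature
sequences carrying miRNA seed sites, and miRNA-gene evidence tables.  A
*planted* sponge is a circRNA that (a) is co-expressed with its miRNAs near a
chosen ECDF quantile of one shared tissue, (b) carries a chosen density of
exact 8mer seed sites for those miRNAs on its mature sequence, and (c) whose
miRNAs have elevated site/publication evidence against the genes of one
target gene set.  Everything is deterministic under a fixed seed and writes
through the package's own readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionPanel,
    GeneSetCollection,
    SequenceSet,
    write_expression_tsv,
    write_fasta,
    write_gmt,
    write_table_tsv,
)

__all__ = ["PlantedSignal", "FixtureConfig", "FixtureBundle", "generate", "default_config"]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class PlantedSignal:
    """One sponge circRNA: its miRNAs, target gene set, and signal strengths."""

    circ_id: str
    mir_ids: list[str]
    target_set_name: str
    coexpression_strength: float = 0.95  # target ECDF quantile; 0 disables the boost
    sites_per_kb: float = 4.0            # planted 8mer density on the mature sequence

    def __post_init__(self) -> None:
        if not 0.0 <= self.coexpression_strength <= 1.0:
            raise ValueError("coexpression_strength must lie in [0, 1]")
        if self.sites_per_kb < 0:
            raise ValueError("sites_per_kb must be non-negative")


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset (seed is mandatory)."""

    seed: int
    n_tissues: int = 5
    n_circ: int = 200
    n_mir: int = 60
    n_gene: int = 500
    n_sets: int = 20
    set_size: int = 25
    planted: list[PlantedSignal] = field(default_factory=list)
    noise_sigma: float = 1.0       # log-normal dispersion of background expression
    zero_fraction: float = 0.3     # per-feature-tissue dropout probability
    circ_len_range: tuple[int, int] = (200, 3000)
    planted_circ_len: int = 500
    mir_len: int = 22
    n_bg_targets_per_mir: int = 30

    def __post_init__(self) -> None:
        ids = {
            "circ": [f"circ_{i + 1:04d}" for i in range(self.n_circ)],
            "mir": [f"mir_{i + 1:04d}" for i in range(self.n_mir)],
            "gene": [f"gene_{i + 1:04d}" for i in range(self.n_gene)],
        }
        set_names = {f"set_{i + 1:02d}" for i in range(self.n_sets)}
        for p in self.planted:
            if p.circ_id not in ids["circ"]:
                raise ValueError(f"planted circRNA {p.circ_id!r} outside universe")
            for m in p.mir_ids:
                if m not in ids["mir"]:
                    raise ValueError(f"planted miRNA {m!r} outside universe")
            if p.target_set_name not in set_names:
                raise ValueError(f"planted target set {p.target_set_name!r} outside universe")

    @property
    def circ_ids(self) -> list[str]:
        return [f"circ_{i + 1:04d}" for i in range(self.n_circ)]

    @property
    def mir_ids(self) -> list[str]:
        return [f"mir_{i + 1:04d}" for i in range(self.n_mir)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{i + 1:04d}" for i in range(self.n_gene)]

    @property
    def tissue_ids(self) -> list[str]:
        return [f"tissue_{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def set_names(self) -> list[str]:
        return [f"set_{i + 1:02d}" for i in range(self.n_sets)]


def default_config(seed: int) -> FixtureConfig:
    """The reference study conditions: 3 planted sponges among 200 circRNAs,
    each sequestering 3 miRNAs aimed at one gene set."""
    planted = [
        PlantedSignal(
            circ_id=f"circ_{i + 1:04d}",
            mir_ids=[f"mir_{3 * i + j + 1:04d}" for j in range(3)],
            target_set_name=f"set_{i + 1:02d}",
        )
        for i in range(3)
    ]
    return FixtureConfig(seed=seed, planted=planted)


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, as in-memory objects."""

    config: FixtureConfig
    circ_expression: ExpressionPanel
    mir_expression: ExpressionPanel
    gene_expression: ExpressionPanel
    circ_sequences: SequenceSet
    mir_sequences: SequenceSet
    targetscan: pd.DataFrame   # mir_id, gene_id, n_sites
    mirtarbase: pd.DataFrame   # mir_id, gene_id, n_publications
    gene_sets: GeneSetCollection
    reference_circs: list[str]

    def write(self, out_dir) -> dict[str, Path]:
        """Write the bundle as the TSV/FASTA/GMT files the CLI reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "circ_expression": out / "circ_expression.tsv",
            "mir_expression": out / "mir_expression.tsv",
            "gene_expression": out / "gene_expression.tsv",
            "circ_fasta": out / "circ_sequences.fasta",
            "mir_fasta": out / "mir_sequences.fasta",
            "targetscan": out / "mir_gene_sites.tsv",
            "mirtarbase": out / "mir_gene_publications.tsv",
            "gmt": out / "gene_sets.gmt",
            "reference": out / "reference_circs.txt",
        }
        write_expression_tsv(self.circ_expression, paths["circ_expression"])
        write_expression_tsv(self.mir_expression, paths["mir_expression"])
        write_expression_tsv(self.gene_expression, paths["gene_expression"])
        write_fasta(self.circ_sequences, paths["circ_fasta"])
        write_fasta(self.mir_sequences, paths["mir_fasta"])
        write_table_tsv(self.targetscan, paths["targetscan"])
        write_table_tsv(self.mirtarbase, paths["mirtarbase"])
        write_gmt(self.gene_sets, paths["gmt"])
        paths["reference"].write_text("".join(c + "\n" for c in self.reference_circs))
        return paths


def _expression_panel(
    rng: np.random.Generator,
    feature_ids: list[str],
    tissue_ids: list[str],
    sigma: float,
    zero_fraction: float,
) -> pd.DataFrame:
    vals = rng.lognormal(mean=2.0, sigma=sigma, size=(len(feature_ids), len(tissue_ids)))
    dropout = rng.random(vals.shape) < zero_fraction
    vals[dropout] = 0.0
    return pd.DataFrame(vals, index=feature_ids, columns=tissue_ids)


def _plant_coexpression(
    rng: np.random.Generator,
    circ_vals: pd.DataFrame,
    mir_vals: pd.DataFrame,
    planted: list[PlantedSignal],
    tissue_ids: list[str],
) -> None:
    """Raise each planted pair to the target ECDF quantile of one shared tissue."""
    for p in planted:
        if p.coexpression_strength <= 0:
            continue
        tissue = tissue_ids[int(rng.integers(len(tissue_ids)))]
        for vals, fid in [(circ_vals, p.circ_id)] + [(mir_vals, m) for m in p.mir_ids]:
            col = vals[tissue].to_numpy()
            expressed = col[col > 0]
            if expressed.size == 0:
                target = 1.0
            elif p.coexpression_strength >= 1.0:
                target = float(expressed.max())  # tie with the maximum -> ECDF score 1
            else:
                target = float(np.quantile(expressed, p.coexpression_strength))
            vals.loc[fid, tissue] = max(target, np.nextafter(0, 1))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])


def _plant_sites(
    rng: np.random.Generator, seq: str, mir_seq: str, n_sites: int
) -> str:
    """Overwrite non-overlapping stretches with exact 8mer sites for the miRNA."""
    site = (
        _COMPLEMENT[mir_seq[7]]
        + "".join(_COMPLEMENT[b] for b in reversed(mir_seq[1:7]))
        + "A"
    )
    L = len(seq)
    if n_sites * len(site) > L:
        raise ValueError(
            f"cannot plant {n_sites} sites of {len(site)} nt into a {L}-nt sequence"
        )
    chars = list(seq)
    occupied: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    while placed < n_sites:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place planted sites without overlap")
        start = int(rng.integers(0, L - len(site) + 1))
        if any(start < e and start + len(site) > s for s, e in occupied):
            continue
        chars[start : start + len(site)] = site
        occupied.append((start, start + len(site)))
        placed += 1
    return "".join(chars)


def generate(config: FixtureConfig) -> FixtureBundle:
    """Generate the full input bundle for one seed (byte-reproducible)."""
    rng = np.random.default_rng(config.seed)

    circ_vals = _expression_panel(
        rng, config.circ_ids, config.tissue_ids, config.noise_sigma, config.zero_fraction
    )
    mir_vals = _expression_panel(
        rng, config.mir_ids, config.tissue_ids, config.noise_sigma, config.zero_fraction
    )
    gene_vals = _expression_panel(
        rng, config.gene_ids, config.tissue_ids, config.noise_sigma, config.zero_fraction
    )
    _plant_coexpression(rng, circ_vals, mir_vals, config.planted, config.tissue_ids)

    # sequences: miRNAs first so planted sites can be derived from them
    mir_records = {m: _random_seq(rng, config.mir_len) for m in config.mir_ids}
    lo, hi = config.circ_len_range
    planted_circ = {p.circ_id: p for p in config.planted}
    circ_records: dict[str, str] = {}
    for cid in config.circ_ids:
        if cid in planted_circ:
            length = config.planted_circ_len
        else:
            length = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        seq = _random_seq(rng, length)
        if cid in planted_circ:
            p = planted_circ[cid]
            n_sites = int(round(p.sites_per_kb * length / 1000.0))
            for m in p.mir_ids:
                seq = _plant_sites(rng, seq, mir_records[m], n_sites)
        circ_records[cid] = seq

    # miRNA-gene evidence: sparse background plus elevated planted evidence
    gene_arr = np.array(config.gene_ids)
    ts_rows: list[tuple[str, str, int]] = []
    mtb_rows: list[tuple[str, str, int]] = []
    for m in config.mir_ids:
        targets = rng.choice(
            gene_arr, size=min(config.n_bg_targets_per_mir, len(gene_arr)), replace=False
        )
        for g in targets:
            ts_rows.append((m, str(g), int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                mtb_rows.append((m, str(g), int(rng.integers(1, 3))))

    # gene sets (sampled after background so planted evidence can reference them)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for name in config.set_names:
        members = rng.choice(gene_arr, size=min(config.set_size, len(gene_arr)), replace=False)
        sets[name] = ("synthetic gene set", frozenset(str(g) for g in members))
    gene_sets = GeneSetCollection(sets=sets)

    for p in config.planted:
        if p.sites_per_kb <= 0 and p.coexpression_strength <= 0:
            continue
        for m in p.mir_ids:
            for g in sorted(gene_sets.members(p.target_set_name)):
                ts_rows.append((m, g, int(rng.integers(4, 8))))
                mtb_rows.append((m, g, int(rng.integers(5, 10))))

    targetscan = (
        pd.DataFrame(ts_rows, columns=["mir_id", "gene_id", "n_sites"])
        .groupby(["mir_id", "gene_id"], as_index=False)["n_sites"].sum()
        .sort_values(["mir_id", "gene_id"]).reset_index(drop=True)
    )
    mirtarbase = (
        pd.DataFrame(mtb_rows, columns=["mir_id", "gene_id", "n_publications"])
        .groupby(["mir_id", "gene_id"], as_index=False)["n_publications"].sum()
        .sort_values(["mir_id", "gene_id"]).reset_index(drop=True)
    )

    return FixtureBundle(
        config=config,
        circ_expression=ExpressionPanel(circ_vals, "circRNA", "SRPBM"),
        mir_expression=ExpressionPanel(mir_vals, "miRNA", "CPM"),
        gene_expression=ExpressionPanel(gene_vals, "gene", "CPM"),
        circ_sequences=SequenceSet(records=circ_records),
        mir_sequences=SequenceSet(records=mir_records),
        targetscan=targetscan,
        mirtarbase=mirtarbase,
        gene_sets=gene_sets,
        reference_circs=[p.circ_id for p in config.planted],
    )
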