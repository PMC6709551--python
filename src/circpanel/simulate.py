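"""Synthetic multi-tool circRNA panel generator with a machine-readable truth table.

Emulates the statistical structure of a large cancer cell-line circRNA
panel so every pipeline stage is testable without any sequencing data:

* cell lines grouped into lineages, with per-line library sizes;
* true circRNAs, most restricted to a single lineage (mirroring the
  observed dominance of lineage-specific circRNAs), with negative-binomial
  backsplice read counts that scale with sequencing depth and with a latent
  EMT-like factor;
* several detection tools, each reporting a true junction with its own
  sensitivity and adding low-read false calls drawn from a per-tool decoy
  junction universe disjoint from the true circRNAs (so false calls cannot
  reach tool agreement at default settings; an overlap knob exists to
  stress-test the consensus filter);
* gene expression with planted biogenesis regulators whose expression is
  coupled to the normalized total backsplice load;
* gene annotation with planted "actionable" genes that receive both a
  boosted circRNA-assignment probability and higher RBP peak counts;
* drug response AUC matrices with planted circRNA-drug effects, and a
  binary mutation matrix.

Everything is drawn from a single seeded ``numpy.random.Generator`` in a
fixed order: the same config and seed reproduce every table (and every
written file) byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    PanelMeta,
    write_circ_gene_map,
    write_gene_annotation,
    write_library_sizes,
    write_lineages,
    write_tool_calls,
    read_circ_gene_map,
    read_gene_annotation,
    read_library_sizes,
    read_lineages,
    read_tool_calls,
)

CHROMS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class ToolProfile:
    """One detector: probability of reporting a true circRNA, and the
    expected number of false calls per cell line expressed as a rate per
    true circRNA."""

    name: str
    sensitivity: float
    false_call_rate: float


DEFAULT_TOOLS = (
    ToolProfile("toolA", 0.90, 0.002),
    ToolProfile("toolB", 0.85, 0.002),
    ToolProfile("toolC", 0.80, 0.002),
    ToolProfile("toolD", 0.70, 0.002),
)


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel (defaults = the default run)."""

    seed: int = 0
    n_lineages: int = 5
    lines_per_lineage: int = 40
    n_genes: int = 2000
    n_circ: int = 5000
    tools: tuple[ToolProfile, ...] = DEFAULT_TOOLS
    read_nb_mean: float = 8.0
    read_nb_dispersion: float = 2.0  # math.inf => reads deterministic at round(mean)
    false_read_mean: float = 0.6    # false-call reads = 1 + Poisson(this)
    library_size_range: tuple[int, int] = (20_000_000, 60_000_000)
    frac_lineage_specific: float = 0.75
    presence_rate_specific: float = 0.15
    presence_rate_broad: float = 0.05
    n_regulators: int = 5
    regulator_effect: float = 0.6   # latent Gaussian coupling (Spearman ~ 0.58)
    actionable_frac: float = 0.05
    actionable_circ_boost: float = 4.0
    rbp_peaks_mean_actionable: float = 900.0
    rbp_peaks_mean_background: float = 230.0
    rbp_peaks_dispersion: float = 3.0
    n_drugs: int = 20
    n_planted_drug_effects: int = 5
    planted_circ_prevalence: float = 0.5
    drug_effect_shift: float = 1.0  # in units of drug_noise_sd
    drug_noise_sd: float = 1.0
    n_mutation_genes: int = 50
    mutation_rate: float = 0.1
    emt_effect: float = 0.25        # read-depth loading of the latent EMT factor
    marker_emt_loading: float = 0.8
    expression_noise_sd: float = 1.0
    false_call_overlap: float = 0.0  # prob. a false call comes from a shared pool

    def validate(self) -> None:
        probs = {
            "frac_lineage_specific": self.frac_lineage_specific,
            "presence_rate_specific": self.presence_rate_specific,
            "presence_rate_broad": self.presence_rate_broad,
            "planted_circ_prevalence": self.planted_circ_prevalence,
            "actionable_frac": self.actionable_frac,
            "mutation_rate": self.mutation_rate,
            "false_call_overlap": self.false_call_overlap,
        }
        for tool in self.tools:
            probs[f"sensitivity[{tool.name}]"] = tool.sensitivity
            if tool.false_call_rate < 0:
                raise ConfigurationError(f"false_call_rate < 0 for {tool.name}")
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_lineages", "lines_per_lineage", "n_genes", "n_circ", "n_drugs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.library_size_range[0] < 1 or self.library_size_range[0] > self.library_size_range[1]:
            raise ConfigurationError("invalid library_size_range")
        if self.n_planted_drug_effects > self.n_drugs:
            raise ConfigurationError("more planted drug effects than drugs")
        if not -1.0 < self.regulator_effect < 1.0:
            raise ConfigurationError("regulator_effect must be in (-1, 1)")
        if len({t.name for t in self.tools}) != len(self.tools):
            raise ConfigurationError("tool names must be unique")


@dataclass
class TruthTable:
    """Ground truth of one simulated panel."""

    circ: pd.DataFrame        # circ_id, gene, restricted_lineage, presence_rate
    true_reads: pd.DataFrame  # circ_id x cell_line integer read counts
    genes: pd.DataFrame       # gene, regulator_effect, actionable
    drug_effects: pd.DataFrame  # circ_id, drug, shift


@dataclass
class SyntheticPanel:
    config: PanelConfig
    tool_calls: pd.DataFrame          # combined long table, all tools
    expression: pd.DataFrame          # gene x cell line
    zscores: pd.DataFrame             # gene (+ EMT markers) x cell line
    lineage_of: dict[str, str]
    library_size: dict[str, int]
    annotation: pd.DataFrame          # indexed by gene
    gene_of_circ: dict[str, str]
    drug_auc: pd.DataFrame            # drug x cell line
    mutations: pd.DataFrame           # mutation feature x cell line
    truth: TruthTable

    @property
    def meta(self) -> PanelMeta:
        return PanelMeta(
            lineage_of=dict(self.lineage_of),
            library_size=dict(self.library_size),
            gene_of_circ=dict(self.gene_of_circ),
        )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.library_size)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every table in the formats the pipeline reads; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for tool, sub in self.tool_calls.groupby("tool", sort=True):
            p = outdir / f"tool_calls.{tool}.tsv"
            write_tool_calls(sub, p, dialect="tool_tsv")
            paths[f"tool_calls.{tool}"] = p
        writers = {
            "expression": lambda p: self.expression.to_csv(p, sep="\t", index_label="gene"),
            "zscores": lambda p: self.zscores.to_csv(p, sep="\t", index_label="gene"),
            "lineages": lambda p: write_lineages(self.lineage_of, p),
            "library_sizes": lambda p: write_library_sizes(self.library_size, p),
            "gene_annotation": lambda p: write_gene_annotation(self.annotation, p),
            "circ_gene_map": lambda p: write_circ_gene_map(self.gene_of_circ, p),
            "drug_auc": lambda p: self.drug_auc.to_csv(p, sep="\t", index_label="drug"),
            "mutations": lambda p: self.mutations.to_csv(p, sep="\t", index_label="feature"),
        }
        for name, writer in writers.items():
            p = outdir / f"{name}.tsv"
            writer(p)
            paths[name] = p
        paths.update(write_truth(self.truth, outdir / "truth"))
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if math.isinf(dispersion):
        return np.rint(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def _unique_junctions(rng: np.random.Generator, n: int, taken: set[str]) -> pd.DataFrame:
    """Draw n junctions with canonical ids disjoint from `taken` (and unique)."""
    rows: dict[str, tuple] = {}
    while len(rows) < n:
        need = n - len(rows)
        chrom = rng.choice(len(CHROMS), size=need)
        start = rng.integers(10_000, 200_000_000, size=need)
        length = rng.integers(200, 5_000, size=need)
        strand = rng.choice(["+", "-"], size=need)
        for i in range(need):
            cid = f"{CHROMS[chrom[i]]}:{start[i]}-{start[i] + length[i]}:{strand[i]}"
            if cid not in taken and cid not in rows:
                rows[cid] = (CHROMS[chrom[i]], int(start[i]), int(start[i] + length[i]), strand[i])
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "start", "end", "strand"])
    df.index.name = "circ_id"
    return df


def simulate_panel(cfg: PanelConfig) -> SyntheticPanel:
    """Generate a complete synthetic panel plus its truth table (see module docs)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- cell lines and lineages ------------------------------------------
    lineages = [f"LIN{i + 1:02d}" for i in range(cfg.n_lineages)]
    cells, lineage_of = [], {}
    for lin in lineages:
        for j in range(cfg.lines_per_lineage):
            c = f"{lin}_C{j + 1:02d}"
            cells.append(c)
            lineage_of[c] = lin
    n_lines = len(cells)
    lib = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=n_lines)
    library_size = {c: int(v) for c, v in zip(cells, lib)}
    lib_ref = float(np.sqrt(cfg.library_size_range[0] * cfg.library_size_range[1]))
    depth = lib / lib_ref

    # --- genes and annotation ---------------------------------------------
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    n_actionable = max(1, round(cfg.actionable_frac * cfg.n_genes))
    actionable_idx = rng.choice(cfg.n_genes, size=n_actionable, replace=False)
    actionable = np.zeros(cfg.n_genes, dtype=bool)
    actionable[actionable_idx] = True
    gene_length = np.exp(rng.normal(np.log(30_000), 0.9, size=cfg.n_genes)).astype(np.int64) + 1_000
    exon_count = 1 + rng.poisson(8.0, size=cfg.n_genes)
    exon_frac = rng.beta(2.0, 10.0, size=cfg.n_genes)
    exon_length = np.maximum(1, (gene_length * exon_frac).astype(np.int64))
    rbp_mean = np.where(
        actionable, cfg.rbp_peaks_mean_actionable, cfg.rbp_peaks_mean_background
    )
    rbp_peaks = _draw_nb(rng, rbp_mean, cfg.rbp_peaks_dispersion)

    # --- circRNAs: coordinates, gene assignment, lineage restriction ------
    circ_df = _unique_junctions(rng, cfg.n_circ, taken=set())
    circ_ids = list(circ_df.index)
    weights = np.where(actionable, cfg.actionable_circ_boost, 1.0)
    weights = weights / weights.sum()
    gene_idx = rng.choice(cfg.n_genes, size=cfg.n_circ, p=weights)
    gene_of_circ = {cid: genes[g] for cid, g in zip(circ_ids, gene_idx)}

    n_restricted = round(cfg.frac_lineage_specific * cfg.n_circ)
    restricted = np.zeros(cfg.n_circ, dtype=bool)
    restricted[rng.choice(cfg.n_circ, size=n_restricted, replace=False)] = True
    restriction = np.where(
        restricted, rng.choice(lineages, size=cfg.n_circ), ""
    ).astype(object)

    # planted drug-effect circRNAs: broad, with boosted prevalence so the
    # median split yields balanced groups
    broad_idx = np.flatnonzero(~restricted)
    n_planted = min(cfg.n_planted_drug_effects, len(broad_idx))
    planted_circ_idx = rng.choice(broad_idx, size=n_planted, replace=False)

    presence_rate = np.where(
        restricted, cfg.presence_rate_specific, cfg.presence_rate_broad
    ).astype(float)
    presence_rate[planted_circ_idx] = cfg.planted_circ_prevalence

    # --- latent EMT factor, presence, true reads --------------------------
    emt = rng.normal(0.0, 1.0, size=n_lines)
    line_lineage = np.array([lineage_of[c] for c in cells])
    allowed = np.ones((cfg.n_circ, n_lines), dtype=bool)
    allowed[restricted] = restriction[restricted, None] == line_lineage[None, :]
    present = allowed & (rng.random((cfg.n_circ, n_lines)) < presence_rate[:, None])

    line_factor = depth * np.exp(cfg.emt_effect * emt)
    read_mean = np.broadcast_to(cfg.read_nb_mean * line_factor, (cfg.n_circ, n_lines))
    reads = _draw_nb(rng, read_mean, cfg.read_nb_dispersion)
    reads = np.where(present, reads, 0)

    true_reads = pd.DataFrame(reads, index=pd.Index(circ_ids, name="circ_id"), columns=cells)

    # --- tool calls --------------------------------------------------------
    frames = []
    shared_decoys = _unique_junctions(
        rng, max(200, cfg.n_circ // 4), taken=set(circ_ids)
    )
    decoy_taken = set(circ_ids) | set(shared_decoys.index)
    for tool in cfg.tools:
        detected = (reads > 0) & (rng.random((cfg.n_circ, n_lines)) < tool.sensitivity)
        ci, li = np.nonzero(detected)
        true_part = pd.DataFrame(
            {
                "tool": tool.name,
                "cell_line": np.asarray(cells, dtype=object)[li],
                "chrom": circ_df["chrom"].to_numpy()[ci],
                "start": circ_df["start"].to_numpy()[ci],
                "end": circ_df["end"].to_numpy()[ci],
                "strand": circ_df["strand"].to_numpy()[ci],
                "reads": reads[ci, li],
                "circ_id": np.asarray(circ_ids, dtype=object)[ci],
            }
        )
        decoys = _unique_junctions(rng, max(200, cfg.n_circ // 4), taken=decoy_taken)
        decoy_taken |= set(decoys.index)
        n_false = rng.poisson(tool.false_call_rate * cfg.n_circ, size=n_lines)
        total = int(n_false.sum())
        if total:
            use_shared = rng.random(total) < cfg.false_call_overlap
            own_idx = rng.integers(0, len(decoys), size=total)
            shared_idx = rng.integers(0, len(shared_decoys), size=total)
            fr = 1 + rng.poisson(cfg.false_read_mean, size=total)
            cell_rep = np.repeat(np.asarray(cells, dtype=object), n_false)

            def _gather(src: pd.DataFrame, idx: np.ndarray, col: str) -> np.ndarray:
                return src[col].to_numpy()[idx]

            def _cols(src, idx, which):
                return {
                    "chrom": _gather(src, idx, "chrom"),
                    "start": _gather(src, idx, "start"),
                    "end": _gather(src, idx, "end"),
                    "strand": _gather(src, idx, "strand"),
                    "circ_id": src.index.to_numpy()[idx],
                    "cell_line": cell_rep[which],
                    "reads": fr[which],
                }

            parts = []
            if (~use_shared).any():
                parts.append(pd.DataFrame(_cols(decoys, own_idx[~use_shared], ~use_shared)))
            if use_shared.any():
                parts.append(pd.DataFrame(_cols(shared_decoys, shared_idx[use_shared], use_shared)))
            false_part = pd.concat(parts, ignore_index=True)
            false_part["tool"] = tool.name
            false_part = false_part.drop_duplicates(subset=["cell_line", "circ_id"])
            frames.append(false_part[true_part.columns])
        frames.append(true_part)
    tool_calls = pd.concat(frames, ignore_index=True)
    tool_calls = tool_calls.sort_values(
        ["tool", "cell_line", "chrom", "start", "end", "strand"]
    ).reset_index(drop=True)

    # --- expression with planted regulators -------------------------------
    norm_load = reads.sum(axis=0) * 1e6 / lib
    z_load = (norm_load - norm_load.mean()) / norm_load.std()
    base_mean = rng.normal(5.0, 2.0, size=cfg.n_genes)
    expr = base_mean[:, None] + rng.normal(
        0.0, cfg.expression_noise_sd, size=(cfg.n_genes, n_lines)
    )
    n_reg = min(cfg.n_regulators, cfg.n_genes)
    regulator_idx = rng.choice(cfg.n_genes, size=n_reg, replace=False)
    rho = cfg.regulator_effect
    reg_effect = np.zeros(cfg.n_genes)
    for g in regulator_idx:
        eps = rng.normal(0.0, 1.0, size=n_lines)
        expr[g] = base_mean[g] + (rho * z_load + math.sqrt(1 - rho**2) * eps)
        reg_effect[g] = rho
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=cells)

    annotation = pd.DataFrame(
        {
            "gene_length": gene_length,
            "exon_count": exon_count,
            "exon_length": exon_length,
            "intron_length": gene_length - exon_length,
            "mean_expression": expression.mean(axis=1).to_numpy(),
            "rbp_peaks": rbp_peaks,
            "actionable": actionable,
        },
        index=pd.Index(genes, name="gene"),
    )

    # --- z-scores (panel genes z-scored per gene; EMT markers coupled) ----
    zmat = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
    from .biogenesis import EPITHELIAL_MARKERS, MESENCHYMAL_MARKERS

    lam = cfg.marker_emt_loading
    marker_rows, marker_names = [], []
    for name in MESENCHYMAL_MARKERS:
        marker_rows.append(lam * emt + math.sqrt(1 - lam**2) * rng.normal(size=n_lines))
        marker_names.append(name)
    for name in EPITHELIAL_MARKERS:
        marker_rows.append(-lam * emt + math.sqrt(1 - lam**2) * rng.normal(size=n_lines))
        marker_names.append(name)
    zscores = pd.DataFrame(
        np.vstack([zmat, np.array(marker_rows)]),
        index=pd.Index(genes + marker_names, name="gene"),
        columns=cells,
    )

    # --- drug response with planted effects -------------------------------
    drugs = [f"DRUG{d + 1:02d}" for d in range(cfg.n_drugs)]
    drug_mu = rng.uniform(4.0, 12.0, size=cfg.n_drugs)
    auc = drug_mu[:, None] + rng.normal(0.0, cfg.drug_noise_sd, size=(cfg.n_drugs, n_lines))
    planted_drug_idx = rng.choice(cfg.n_drugs, size=n_planted, replace=False)
    drug_rows = []
    shift = cfg.drug_effect_shift * cfg.drug_noise_sd
    for ci, di in zip(planted_circ_idx, planted_drug_idx):
        mask = present[ci]
        auc[di, mask] += shift
        drug_rows.append((circ_ids[ci], drugs[di], shift))
    auc = np.maximum(auc, 0.0)
    drug_auc = pd.DataFrame(auc, index=pd.Index(drugs, name="drug"), columns=cells)

    # --- mutations ---------------------------------------------------------
    n_mut = min(cfg.n_mutation_genes, cfg.n_genes)
    mut_gene_idx = rng.choice(cfg.n_genes, size=n_mut, replace=False)
    mut = (rng.random((n_mut, n_lines)) < cfg.mutation_rate).astype(int)
    mutations = pd.DataFrame(
        mut,
        index=pd.Index([f"MUT_{genes[g]}" for g in mut_gene_idx], name="feature"),
        columns=cells,
    )

    truth = TruthTable(
        circ=pd.DataFrame(
            {
                "circ_id": circ_ids,
                "gene": [gene_of_circ[c] for c in circ_ids],
                "restricted_lineage": restriction,
                "presence_rate": presence_rate,
            }
        ),
        true_reads=true_reads,
        genes=pd.DataFrame(
            {"gene": genes, "regulator_effect": reg_effect, "actionable": actionable}
        ),
        drug_effects=pd.DataFrame(drug_rows, columns=["circ_id", "drug", "shift"]),
    )

    return SyntheticPanel(
        config=cfg,
        tool_calls=tool_calls,
        expression=expression,
        zscores=zscores,
        lineage_of=lineage_of,
        library_size=library_size,
        annotation=annotation,
        gene_of_circ=gene_of_circ,
        drug_auc=drug_auc,
        mutations=mutations,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------


def write_truth(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_circ": outdir / "circ.tsv",
        "truth_reads": outdir / "true_reads.tsv",
        "truth_genes": outdir / "genes.tsv",
        "truth_drug_effects": outdir / "drug_effects.tsv",
    }
    truth.circ.to_csv(paths["truth_circ"], sep="\t", index=False)
    truth.true_reads.to_csv(paths["truth_reads"], sep="\t", index_label="circ_id")
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.drug_effects.to_csv(paths["truth_drug_effects"], sep="\t", index=False)
    return paths


def read_truth(outdir: str | Path) -> TruthTable:
    outdir = Path(outdir)
    circ = pd.read_csv(outdir / "circ.tsv", sep="\t", dtype={"circ_id": str})
    circ["restricted_lineage"] = circ["restricted_lineage"].fillna("").astype(object)
    return TruthTable(
        circ=circ,
        true_reads=pd.read_csv(outdir / "true_reads.tsv", sep="\t", index_col="circ_id"),
        genes=pd.read_csv(outdir / "genes.tsv", sep="\t"),
        drug_effects=pd.read_csv(outdir / "drug_effects.tsv", sep="\t"),
    )


def read_panel_inputs(indir: str | Path) -> dict:
    """Load a written panel directory back into pipeline-ready tables."""
    indir = Path(indir)
    calls = []
    for p in sorted(indir.glob("tool_calls.*.tsv")):
        tool = p.name.split(".")[1]
        calls.append(read_tool_calls(p, dialect="tool_tsv", tool=tool))
    out = {
        "tool_calls": pd.concat(calls, ignore_index=True) if calls else pd.DataFrame(),
        "expression": pd.read_csv(indir / "expression.tsv", sep="\t", index_col="gene"),
        "zscores": pd.read_csv(indir / "zscores.tsv", sep="\t", index_col="gene"),
        "lineage_of": read_lineages(indir / "lineages.tsv"),
        "library_size": read_library_sizes(indir / "library_sizes.tsv"),
        "annotation": read_gene_annotation(indir / "gene_annotation.tsv"),
        "gene_of_circ": read_circ_gene_map(indir / "circ_gene_map.tsv"),
        "drug_auc": pd.read_csv(indir / "drug_auc.tsv", sep="\t", index_col="drug"),
        "mutations": pd.read_csv(indir / "mutations.tsv", sep="\t", index_col="feature"),
    }
    if (indir / "truth").exists():
        out["truth"] = read_truth(indir / "truth")
    return out
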