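"""End-to-end orchestration from one YAML config.

Stages: rate estimation -> ERC (normalize, correlate, bootstrap
differences), dN/dS group comparisons, contact-pair detection,
substitution ordering, and site selection. Each stage can run from user
files (FASTA alignments, a Newick tree, a PDB structure, TSV tables) or
from the synthetic generator; every table is written as a standalone
TSV next to a JSON metadata record of the seeds used, so each report
number can be re-derived from the stage outputs.

A "printed-counts" entry point reproduces the ordering statistics from
externally obtained contingency counts alone, without any sequence data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import dnds as dnds_mod
from . import erc as erc_mod
from . import ordering as ordering_mod
from . import rates as rates_mod
from . import selection as selection_mod
from . import simulate as sim_mod
from .core import Alignment, InvalidInputError, Phylogeny

logger = logging.getLogger("mitonuc.pipeline")


class ConfigError(ValueError):
    """Config validation failed; carries every violation found."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


_SYNTH_DEFAULTS = dict(
    n_taxa=60, seq_length=500, rate_coupling_rho=0.9, scalar_sd=0.5,
    base_rate=0.02, kappa=2.0, compensation_boost_beta=20.0,
    compensation_direction="mt_triggers_n", n_background_genes=15,
    n_pairs=300, tree_shape="star", omega_by_geneset=None)

_DEFAULTS = dict(
    seed=0, output_dir="mitonuc_out",
    stages=["erc", "dnds", "ordering", "selection"],
    erc=dict(n_boot=10000, ci="bca", min_subset_size=5),
    dnds=dict(codes={"mt": dnds_mod.VERTEBRATE_MITO_CODE,
                     "default": dnds_mod.STANDARD_CODE}),
    contacts=dict(cutoff=5.0, criterion="distance", overlap_threshold=-1.0),
    ordering=dict(method="fitch", close_max_separation=2),
    selection=dict(alpha=0.05, stringent_alpha=0.01, fnm_threshold=0.05),
    synthetic=_SYNTH_DEFAULTS,
    files={},
)


@dataclass
class PipelineConfig:
    raw: dict
    path: str | None = None

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])


def _merge(defaults, user):
    out = dict(defaults)
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(source) -> PipelineConfig:
    """Parse and validate a YAML config, reporting every violation.

    ``source`` may be a path or an already-parsed dict. Defaults are
    filled for everything not supplied.
    """
    path = None
    if isinstance(source, (str, Path)):
        path = str(source)
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    cfg = _merge(_DEFAULTS, user)

    violations: list[str] = []
    if not isinstance(cfg["seed"], int):
        violations.append("seed: must be an integer")
    if cfg["erc"]["n_boot"] < 2:
        violations.append("erc.n_boot: must be >= 2")
    if cfg["contacts"]["cutoff"] <= 0:
        violations.append("contacts.cutoff: must be > 0")
    for fld in ("alpha", "stringent_alpha", "fnm_threshold"):
        v = cfg["selection"][fld]
        if not 0 <= v <= 1:
            violations.append(f"selection.{fld}: must be in [0, 1]")
    syn = cfg["synthetic"]
    if not -1 <= syn["rate_coupling_rho"] <= 1:
        violations.append("synthetic.rate_coupling_rho: must be in [-1, 1]")
    if syn["compensation_boost_beta"] < 1:
        violations.append("synthetic.compensation_boost_beta: must be >= 1")
    if syn["tree_shape"] not in ("star", "yule"):
        violations.append("synthetic.tree_shape: must be star or yule")
    unknown_stages = set(cfg["stages"]) - {"erc", "dnds", "contacts",
                                           "ordering", "selection"}
    if unknown_stages:
        violations.append(f"stages: unknown {sorted(unknown_stages)}")
    for key, p in (cfg.get("files") or {}).items():
        if p and not Path(p).exists():
            violations.append(f"files.{key}: path {p!r} does not exist")
    if violations:
        raise ConfigError(violations)
    return PipelineConfig(cfg, path)


@dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        with open(out_dir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Synthetic inputs
# ---------------------------------------------------------------------------

def star_newick(n_taxa: int, length: float = 1.0) -> str:
    """Star phylogeny: the exchangeable-lineages calibration baseline."""
    width = max(3, len(str(n_taxa)))
    tips = ",".join(f"t{i:0{width}d}:{length:g}" for i in range(1, n_taxa + 1))
    return f"({tips});"


def _sim_config(config: PipelineConfig, **overrides) -> sim_mod.SimulationConfig:
    syn = config["synthetic"]
    kwargs = dict(
        n_taxa=syn["n_taxa"], seq_length=syn["seq_length"],
        rate_coupling_rho=syn["rate_coupling_rho"],
        scalar_sd=syn["scalar_sd"], base_rate=syn["base_rate"],
        kappa=syn["kappa"],
        compensation_boost_beta=syn["compensation_boost_beta"],
        compensation_direction=syn["compensation_direction"],
        n_background_genes=syn["n_background_genes"], seed=config.seed)
    if syn.get("omega_by_geneset"):
        kwargs["omega_by_geneset"] = dict(syn["omega_by_geneset"])
    kwargs.update(overrides)
    return sim_mod.SimulationConfig(**kwargs)


def _synthetic_tree(config: PipelineConfig) -> Phylogeny:
    syn = config["synthetic"]
    if syn["tree_shape"] == "star":
        return Phylogeny.from_newick(star_newick(syn["n_taxa"]))
    return sim_mod.generate_yule_tree(syn["n_taxa"], config.seed)


# ---------------------------------------------------------------------------
# ERC stage
# ---------------------------------------------------------------------------

def run_erc_pipeline(config: PipelineConfig,
                     rate_vectors=None) -> AnalysisReport:
    """Normalized-rate correlations and bootstrap difference tests.

    With ``rate_vectors`` (gene_set -> RateVector, including ``nrand1``
    and ``nrand2`` backgrounds) the stage runs on user data; otherwise
    rates are generated: mt and N-mt coupled at the configured rho,
    a control set uncoupled, both backgrounds independent.
    """
    seed = config.seed
    scfg = _sim_config(config)
    if rate_vectors is None:
        tree = _synthetic_tree(config)
        pair = sim_mod.draw_branch_scalars(
            tree, scfg.rate_coupling_rho, scfg.scalar_sd, seed)
        control = sim_mod.draw_branch_scalars(tree, 0.0, scfg.scalar_sd,
                                              seed + 1)
        bg1 = sim_mod.draw_background_scalars(
            tree, scfg.scalar_sd, scfg.n_background_genes, seed, "nrand1")
        bg2 = sim_mod.draw_background_scalars(
            tree, scfg.scalar_sd, scfg.n_background_genes, seed, "nrand2")
        rate_vectors = {
            "mt": sim_mod.tip_rates(tree, {b: v[0] for b, v in pair.items()},
                                    "mt", scfg.base_rate),
            "nmt": sim_mod.tip_rates(tree, {b: v[1] for b, v in pair.items()},
                                     "nmt", scfg.base_rate),
            "control": sim_mod.tip_rates(
                tree, {b: v[1] for b, v in control.items()}, "control",
                scfg.base_rate),
            "nrand1": sim_mod.tip_rates(tree, bg1, "nrand1", scfg.base_rate),
            "nrand2": sim_mod.tip_rates(tree, bg2, "nrand2", scfg.base_rate),
        }

    # Nrand1 normalizes mt; Nrand2 normalizes every nuclear target —
    # never the same half for both sides of a correlation.
    mt_norm = erc_mod.normalize_rates(rate_vectors["mt"],
                                      rate_vectors["nrand1"])
    targets = {k: erc_mod.normalize_rates(v, rate_vectors["nrand2"])
               for k, v in rate_vectors.items()
               if k not in ("mt", "nrand1", "nrand2")}

    rows = []
    normalized = {}
    for name, norm in targets.items():
        res = erc_mod.spearman_erc(mt_norm, norm)
        rows.append(dict(target=name, r_s=res.r_s, n=res.n,
                         p_value=res.p_value, method="spearman"))
        normalized[name] = norm
    erc_table = pd.DataFrame(rows)

    diff_rows = []
    names = list(targets)
    if len(names) >= 2:
        res = erc_mod.bootstrap_difference(
            mt_norm, normalized[names[0]], normalized[names[1]],
            n_boot=config["erc"]["n_boot"], ci=config["erc"]["ci"],
            seed=seed)
        diff_rows.append(dict(
            set_a=names[0], set_b=names[1], delta_r_s=res.delta_r_s,
            ci_lo=res.ci[0], ci_hi=res.ci[1], n_boot=res.n_boot,
            ci_type=res.ci_type, robust=res.robust))
    report = AnalysisReport(
        tables={"erc_correlations": erc_table,
                "erc_differences": pd.DataFrame(diff_rows)},
        metadata={"stage": "erc", "seed": seed,
                  "n_boot": config["erc"]["n_boot"]})
    return report


# ---------------------------------------------------------------------------
# Rates stage (file-driven)
# ---------------------------------------------------------------------------

def run_rates_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Fixed-topology branch lengths and root-to-tip rates from files.

    Needs ``files.tree`` (Newick) and ``files.alignments`` (directory of
    per-gene-set amino-acid FASTA files; the file stem is the gene-set
    label). Writes a rates TSV and a length-annotated Newick per set.
    """
    files = config.get("files") or {}
    if not files.get("tree") or not files.get("alignments"):
        raise InvalidInputError(
            "rates stage needs files.tree and files.alignments")
    topology = Phylogeny.from_newick_file(files["tree"])
    aln_dir = Path(files["alignments"])
    fastas = sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa"))
    if not fastas:
        raise InvalidInputError(f"no FASTA files in {aln_dir}")
    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in fastas:
        gene_set = path.stem
        aln = Alignment.from_fasta(path, gene_set=gene_set)
        topo = topology.copy()
        fitted = rates_mod.estimate_branch_lengths(aln, topo)
        fitted.to_newick_file(out_dir / f"{gene_set}.lengths.nwk")
        vec = rates_mod.root_to_tip_distances(fitted, gene_set)
        rows.extend(dict(taxon=t, gene_set=gene_set, distance=d)
                    for t, d in vec.values.items())
        logger.info("rates: %s fitted (%d taxa)", gene_set, aln.n_taxa)
    return AnalysisReport(
        tables={"root_to_tip_rates": pd.DataFrame(rows)},
        metadata={"stage": "rates", "tree": str(files["tree"])})


# ---------------------------------------------------------------------------
# dN/dS stage
# ---------------------------------------------------------------------------

def run_dnds_pipeline(config: PipelineConfig,
                      alignments: dict[str, Alignment] | None = None,
                      groups: dict[str, str] | None = None,
                      n_genes_per_set: int = 6) -> AnalysisReport:
    """Gene-wise NG86 omega and Tukey HSD group comparisons.

    With user ``alignments`` (gene -> codon Alignment) and ``groups``
    (gene -> set label) the stage runs on real data; otherwise it
    simulates ``n_genes_per_set`` genes for each configured gene set.
    """
    seed = config.seed
    codes = config["dnds"]["codes"]
    scfg = _sim_config(config)
    if alignments is None:
        tree = sim_mod.generate_yule_tree(min(scfg.n_taxa, 20), seed)
        scalars = {b: 1.0 for b in tree.branch_ids}
        alignments, groups = {}, {}
        for gs, omega in scfg.omega_by_geneset.items():
            for k in range(n_genes_per_set):
                gene = f"{gs}_{k}"
                gcfg = _sim_config(config, seed=seed + 104729 * (k + 1))
                aln, _ = sim_mod.simulate_alignment(
                    tree, scalars, scfg.seq_length, "codon", gcfg,
                    gene_set=gs, stage=f"dnds:{gene}")
                aln.gene_set = gene
                alignments[gene] = aln
                groups[gene] = gs

    rows = []
    omega_by_gene = {}
    for gene, aln in alignments.items():
        gs = groups.get(gene, "default")
        table_id = codes.get(gs, codes.get("default",
                                           dnds_mod.STANDARD_CODE))
        res = dnds_mod.geneset_dnds(aln, table_id, gene)
        rows.append(dict(gene=gene, group=gs, d_n=res.d_n, d_s=res.d_s,
                         omega=res.omega, n_pairs=res.n_pairs,
                         n_saturated=res.n_saturated,
                         saturated=res.saturated))
        if not res.saturated and res.omega is not None:
            omega_by_gene[gene] = res.omega
    dnds_table = pd.DataFrame(rows)

    comp_rows = []
    try:
        comps = dnds_mod.compare_groups(omega_by_gene, groups)
        comp_rows = [dict(group_a=c.group_a, group_b=c.group_b,
                          difference=c.mean_difference,
                          p_adjusted=c.p_adjusted) for c in comps]
    except InvalidInputError as exc:
        logger.warning("group comparison skipped: %s", exc)
    return AnalysisReport(
        tables={"dnds_genes": dnds_table,
                "dnds_group_comparisons": pd.DataFrame(comp_rows)},
        metadata={"stage": "dnds", "seed": seed})


# ---------------------------------------------------------------------------
# Contacts stage
# ---------------------------------------------------------------------------

def run_contacts_pipeline(config: PipelineConfig) -> AnalysisReport:
    files = config.get("files") or {}
    if not files.get("structure") or not files.get("chain_map"):
        raise InvalidInputError(
            "contacts stage needs files.structure and files.chain_map")
    chain_map = pd.read_csv(files["chain_map"], sep="\t")
    chain_to_gene = dict(zip(chain_map["chain"], chain_map["gene"]))
    gene_to_genome = dict(zip(chain_map["gene"], chain_map["genome"]))
    structure = contacts_mod.parse_structure(
        files["structure"], chain_to_gene, gene_to_genome)
    pairs = contacts_mod.find_contact_pairs(
        structure, cutoff=config["contacts"]["cutoff"],
        criterion=config["contacts"]["criterion"],
        overlap_threshold=config["contacts"]["overlap_threshold"])
    rows = [dict(mt_gene=p.mt_gene, mt_residue=p.mt_residue,
                 n_gene=p.n_gene, n_residue=p.n_residue,
                 distance_A=round(p.distance, 3)) for p in pairs]
    return AnalysisReport(
        tables={"contact_pairs": pd.DataFrame(rows)},
        metadata={"stage": "contacts",
                  "cutoff": config["contacts"]["cutoff"]})


# ---------------------------------------------------------------------------
# Ordering stage
# ---------------------------------------------------------------------------

def run_ordering_pipeline(config: PipelineConfig,
                          inputs=None) -> AnalysisReport:
    """Reconstruction -> events -> pair records -> ordering tests.

    ``inputs`` may supply (mt_alignment, nmt_alignment, tree, pairs);
    otherwise a compensatory simulation provides them along with truth
    labels for the report.
    """
    seed = config.seed
    truth = None
    if inputs is None:
        scfg = _sim_config(config)
        n_pairs = config["synthetic"]["n_pairs"]
        tree = sim_mod.generate_yule_tree(scfg.n_taxa, seed)
        mt_aln, nmt_aln, truth = sim_mod.simulate_compensatory_pairs(
            tree, n_pairs, scfg)
        pairs = [contacts_mod.ContactPair(
            "mt", "", p, "nmt", "", p, 0.0, mt_column=p + 1, n_column=p + 1)
            for p in range(n_pairs)]
    else:
        mt_aln, nmt_aln, tree, pairs = inputs

    method = config["ordering"]["method"]
    st_mt = ordering_mod.reconstruct_ancestral(mt_aln, tree, method)
    st_nm = ordering_mod.reconstruct_ancestral(nmt_aln, tree, method)
    ev_mt = ordering_mod.map_substitutions(st_mt, tree,
                                           mt_aln.gene_set or "mt", "mt")
    ev_nm = ordering_mod.map_substitutions(st_nm, tree,
                                           nmt_aln.gene_set or "nmt",
                                           "nuclear")
    records = ordering_mod.classify_contact_pairs(pairs, ev_mt, ev_nm, tree)
    summary = ordering_mod.ordering_summary(records)

    tests = []
    n_mt, n_nmt = summary["mt_first"], summary["nmt_first"]
    if n_mt + n_nmt > 0:
        chi = ordering_mod.chisq_equal_order(n_mt, n_nmt)
        tests.append(dict(test="chisq_equal_order", scope="all",
                          n_mt_first=n_mt, n_nmt_first=n_nmt,
                          statistic=chi.statistic, p_value=chi.p_value,
                          odds_ratio=None, or_lo=None, or_hi=None))
        close = [r for r in records if r.proximity == "close"]
        far = [r for r in records if r.proximity == "far"]
        if close and far:
            table = [[sum(r.classification == "mt_first" for r in close),
                      sum(r.classification == "nmt_first" for r in close)],
                     [sum(r.classification == "mt_first" for r in far),
                      sum(r.classification == "nmt_first" for r in far)]]
            fr = ordering_mod.fisher_mtfirst_enrichment(table)
            tests.append(dict(test="fisher_close_vs_far", scope="all",
                              n_mt_first=table[0][0],
                              n_nmt_first=table[0][1], statistic=None,
                              p_value=fr.p_value, odds_ratio=fr.odds_ratio,
                              or_lo=fr.or_ci[0] if fr.or_ci else None,
                              or_hi=fr.or_ci[1] if fr.or_ci else None))

    # events TSV with frequency-FNM annotation (derived-residue rarity)
    fnm_threshold = config["selection"]["fnm_threshold"]
    event_rows = []
    for ev, aln in ((ev_mt, mt_aln), (ev_nm, nmt_aln)):
        for e in ev:
            flag = selection_mod.flag_functional_nodal(e, aln,
                                                       fnm_threshold)
            event_rows.append(dict(
                gene=e.gene, genome=e.genome, column=e.column + 1,
                branch=e.branch, depth=e.depth, from_state=e.from_state,
                to_state=e.to_state,
                fnm=None if flag is None else flag.flagged))

    # counts by classification x proximity (ordering summary table)
    cells: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.classification, r.proximity or "n/a")
        cells[key] = cells.get(key, 0) + 1
    summary_rows = [dict(scope="all", classification=c, proximity=p,
                         count=n)
                    for (c, p), n in sorted(cells.items())]

    branch_counts = ordering_mod.branch_substitution_summary(
        ev_mt + ev_nm, tree)
    branch_rows = [dict(branch=b, depth=tree.nodes[b].depth,
                        mt=c["mt"], nmt=c["nmt"], majority=c["majority"])
                   for b, c in sorted(branch_counts.items())]
    rec_rows = [dict(pair_id=r.pair_id, classification=r.classification,
                     separation=r.separation, proximity=r.proximity,
                     n_paths=r.n_paths,
                     true_label=(truth.pair_labels.get(r.pair_id)
                                 if truth else None))
                for r in records]
    meta = {"stage": "ordering", "seed": seed, "method": method,
            "summary": summary}
    if truth is not None:
        labels = list(truth.pair_labels.values())
        meta["truth_labels"] = {k: labels.count(k) for k in
                                ("mt_first", "nmt_first", "same_branch",
                                 "unresolved")}
    return AnalysisReport(
        tables={"ordering_records": pd.DataFrame(rec_rows),
                "ordering_tests": pd.DataFrame(tests),
                "ordering_summary": pd.DataFrame(summary_rows),
                "ordering_events": pd.DataFrame(event_rows),
                "branch_substitutions": pd.DataFrame(branch_rows)},
        metadata=meta)


# ---------------------------------------------------------------------------
# Selection stage
# ---------------------------------------------------------------------------

def run_selection_pipeline(config: PipelineConfig,
                           alignment: Alignment | None = None,
                           tree: Phylogeny | None = None,
                           contact_sites: set[int] | None = None
                           ) -> AnalysisReport:
    """Site-level selection scan with contact-enrichment summary."""
    seed = config.seed
    sel = config["selection"]
    scfg = _sim_config(config)
    if alignment is None:
        tree = sim_mod.generate_yule_tree(min(scfg.n_taxa, 20), seed)
        omega = scfg.omega_by_geneset.get("nmt", 0.2)
        cfg2 = _sim_config(config, base_rate=max(scfg.base_rate, 0.05))
        alignment, _ = sim_mod.simulate_alignment(
            tree, {b: 1.0 for b in tree.branch_ids},
            min(scfg.seq_length, 300), "codon", cfg2, gene_set="nmt",
            stage="selection")
        rng = sim_mod.substream(seed, "selection_contacts")
        n_sites = alignment.length // 3
        contact_sites = set(map(int, rng.choice(
            n_sites, size=max(n_sites // 5, 1), replace=False)))

    states = ordering_mod.reconstruct_ancestral(alignment, tree, "fitch")
    gene = alignment.gene_set or "gene"
    results = selection_mod.scan_sites(
        states, tree, gene, alpha=sel["alpha"],
        stringent_alpha=sel["stringent_alpha"])
    site_rows = [dict(gene=r.gene, site=r.site,
                      contact=(r.site in contact_sites
                               if contact_sites else None),
                      n_changes=r.n_changes, nonsyn=r.nonsyn_changes,
                      p_value=r.p_value, selected=r.selected,
                      stringent=r.stringent) for r in results]
    tables = {"selection_sites": pd.DataFrame(site_rows)}
    if contact_sites is not None:
        partition = {(gene, r.site): ("contact" if r.site in contact_sites
                                      else "non-contact") for r in results}
        props = selection_mod.proportion_selected(results, partition)
        tables["selection_proportions"] = pd.DataFrame(
            [dict(cell=k, **v) for k, v in sorted(props.items())])
        enr = selection_mod.contact_enrichment(
            results, {(gene, r.site): r.site in contact_sites
                      for r in results})
        tables["selection_enrichment"] = pd.DataFrame([dict(
            p_value=enr.p_value, odds_ratio=enr.odds_ratio,
            or_lo=enr.or_ci[0] if enr.or_ci else None,
            or_hi=enr.or_ci[1] if enr.or_ci else None)])
    return AnalysisReport(tables=tables,
                          metadata={"stage": "selection", "seed": seed,
                                    "alpha": sel["alpha"]})


# ---------------------------------------------------------------------------
# Printed-counts entry point and full run
# ---------------------------------------------------------------------------

def printed_counts_report(n_mt_first: int, n_nmt_first: int) -> dict:
    """Ordering statistics from externally obtained counts alone."""
    total = n_mt_first + n_nmt_first
    chi = ordering_mod.chisq_equal_order(n_mt_first, n_nmt_first)
    return {
        "n_mt_first": n_mt_first,
        "n_nmt_first": n_nmt_first,
        "mt_first_percent": round(100.0 * n_mt_first / total, 1),
        "nmt_first_percent": round(100.0 * n_nmt_first / total, 1),
        "chi_square": chi.statistic,
        "df": chi.df,
        "p_value": chi.p_value,
    }


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Run every enabled stage; one combined report, all tables on disk."""
    report = AnalysisReport(metadata={
        "seed": config.seed,
        "stages": list(config["stages"]),
        "seeds_used": {}})
    runners = {"erc": run_erc_pipeline, "dnds": run_dnds_pipeline,
               "contacts": run_contacts_pipeline,
               "ordering": run_ordering_pipeline,
               "selection": run_selection_pipeline}
    for stage in config["stages"]:
        try:
            sub = runners[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report.tables.update(sub.tables)
        report.metadata["seeds_used"][stage] = sub.metadata.get(
            "seed", config.seed)
        report.metadata[stage] = {
            k: v for k, v in sub.metadata.items() if k != "stage"}
    report.write(config.output_dir)
    return report
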