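"""Run configuration and end-to-end pipeline orchestration.

A run executes the enabled stages in fixed order — qc, rank, spatial,
network, termmap — on either user-supplied files or data synthesized by the
bundled generator, writing per-stage outputs plus a JSON manifest of file
hashes. With a fixed config and seed the manifest hashes are identical
between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import abundance, io, network, qc, spatial, synthetic, termmaps
from .digest import CleavageRule
from .errors import ConfigError
from .layout import read_layout, write_layout
from .synthetic import ModChannel, SimulationConfig

log = logging.getLogger("voxelprot")

STAGES = ("qc", "rank", "spatial", "network", "termmap")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled."""

    out_dir: str = "voxelprot_out"
    seed: int = 0
    log_level: str = "INFO"
    # input paths; any left None is synthesized by the generator
    matrix: str | None = None
    peptides: str | None = None
    fasta: str | None = None
    layout: str | None = None
    terms: str | None = None
    stages: tuple[str, ...] = STAGES
    # analysis parameters
    se_cutoff: float = spatial.DEFAULT_SE_CUTOFF
    beta: float | None = None
    mode: str = "unsigned"
    top_k: int = network.DEFAULT_TOP_K
    edge_threshold: float = 0.5
    inverse_threshold: float = 0.6
    cut_height: float = 0.5
    top_n_shifts: int = 8
    term_scale: str = "linear"
    normalize: bool = True
    proline_rule: bool = True
    seed_protein: str | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}")
        if self.mode not in ("unsigned", "signed"):
            raise ConfigError(f"mode must be unsigned|signed, got {self.mode!r}")
        if self.term_scale not in ("linear", "log2"):
            raise ConfigError(f"term_scale must be linear|log2, got {self.term_scale!r}")
        if self.se_cutoff < 0 or self.top_k < 0:
            raise ConfigError("se_cutoff and top_k must be >= 0")
        bad = set(self.simulation) - _SIM_KEYS
        if bad:
            raise ConfigError(f"unknown simulation key(s) {sorted(bad)}")
        for path_field in ("matrix", "peptides", "fasta", "layout", "terms"):
            p = getattr(self, path_field)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{path_field} path does not exist: {p}")
        self.stages = tuple(self.stages)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        if "mod_channels" in kwargs:
            kwargs["mod_channels"] = tuple(
                ModChannel(
                    shift=float(c["shift"]),
                    prob=float(c["prob"]),
                    residue_weights=tuple((str(r), float(w)) for r, w in c["residues"].items()),
                )
                for c in kwargs["mod_channels"]
            )
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name; defaults fill everything omitted.
    """
    with open(path) as fh:  # missing file raises the usual OSError
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "incomplete": False}
        self.rule = CleavageRule() if config.proline_rule else CleavageRule(
            suppress_before=frozenset()
        )

    def register(self, stage: str, path: Path) -> None:
        rel = str(path.relative_to(self.out))
        self.manifest["stages"].setdefault(stage, {})[rel] = _sha256(path)

    def write_text(self, stage: str, name: str, text: str) -> Path:
        path = self.out / name
        path.write_text(text)
        self.register(stage, path)
        return path

    # ---------------- inputs

    def prepare_inputs(self):
        cfg = self.config
        sim = cfg.simulation_config()
        if cfg.layout:
            self.layout = read_layout(cfg.layout)
        else:
            self.layout = sim.layout()
            write_layout(self.layout, self.out / "layout.json")
            self.register("simulate", self.out / "layout.json")
        if cfg.fasta:
            self.proteome = io.read_fasta(cfg.fasta)
        else:
            self.proteome = synthetic.generate_proteome(seed=sim.seed)
            io.write_fasta(self.proteome, self.out / "proteome.fasta")
            self.register("simulate", self.out / "proteome.fasta")
        if cfg.matrix:
            self.matrix = io.read_matrix(cfg.matrix)
            self.matrix_truth = None
        else:
            self.matrix, self.matrix_truth = synthetic.generate_intensity(sim)
            io.write_matrix(self.matrix, self.out / "intensity.tsv")
            self.register("simulate", self.out / "intensity.tsv")
        if cfg.peptides:
            self.records = io.read_peptides(cfg.peptides)
            self.peptide_truth = None
        else:
            self.records, self.peptide_truth = synthetic.generate_peptide_table(
                sim, self.proteome
            )
            io.write_peptides(self.records, self.out / "peptides.tsv")
            self.register("simulate", self.out / "peptides.tsv")
        if self.matrix_truth is not None:
            self.matrix_truth.to_json(self.out / "ground_truth.json")
            self.register("simulate", self.out / "ground_truth.json")
        self.terms = io.read_terms(cfg.terms) if cfg.terms else None
        self.sim = sim

    # ---------------- stages

    def stage_qc(self):
        rule = self.rule
        semi = qc.semi_tryptic_fraction(self.records, rule)
        mis = qc.miscleavage_fraction(self.records, rule)
        kr_c, kr_up = qc.kr_cleavage_ratio(self.records, rule)
        shifts = qc.mass_shift_table(self.records, top_n=self.config.top_n_shifts)
        strata, conditional = qc.miscleavage_modification_stratification(self.records, rule)
        semi.rename("semi_tryptic_fraction").rename_axis("voxel").to_csv(
            self.out / "qc_semi_tryptic.tsv", sep="\t"
        )
        mis.rename("miscleavage_fraction").rename_axis("voxel").to_csv(
            self.out / "qc_miscleavage.tsv", sep="\t"
        )
        shifts.to_csv(self.out / "qc_mass_shifts.tsv", sep="\t", index=False)
        for name in ("qc_semi_tryptic.tsv", "qc_miscleavage.tsv", "qc_mass_shifts.tsv"):
            self.register("qc", self.out / name)
        summary = {
            "semi_tryptic_pooled": qc.semi_tryptic_fraction(self.records, rule, per_voxel=False),
            "miscleavage_pooled": qc.miscleavage_fraction(self.records, rule, per_voxel=False),
            "kr_ratio_c_term": kr_c,
            "kr_ratio_upstream": kr_up,
            "stratification": strata.to_dict(),
            "conditional_miscleaved_modified": conditional.to_dict(),
        }
        self.write_text("qc", "qc_summary.json", json.dumps(summary, indent=1) + "\n")

    def stage_rank(self):
        counts = abundance.sum_spectral_counts(self.records)
        ranked = abundance.rank_proteins(counts)
        ranked.to_csv(self.out / "rank_table.tsv", sep="\t", index=False)
        self.register("rank", self.out / "rank_table.tsv")
        replicate = synthetic.generate_spectral_counts(self.sim, self.records, resample=True)
        record_counts = synthetic.generate_spectral_counts(self.sim, self.records)
        subset = set(record_counts.index[record_counts >= 5])
        if len(subset) >= 3:
            rho = abundance.rank_concordance(record_counts, replicate, subset)
            self.write_text(
                "rank",
                "rank_concordance.json",
                json.dumps({"spearman": rho, "n_subset": len(subset)}) + "\n",
            )

    def stage_spatial(self):
        m = spatial.fully_quantified(self.matrix)
        if self.config.normalize:
            m = spatial.quantile_normalize(m)
        result = spatial.se_filter(m, self.config.se_cutoff)
        self.filtered_matrix = m
        self.se_result = result
        io.write_matrix(m, self.out / "matrix_fully_quantified.tsv")
        result.se.rename("se").rename_axis("protein").to_csv(
            self.out / "spatial_se.tsv", sep="\t"
        )
        (self.out / "spatial_retained.txt").write_text(
            "".join(p + "\n" for p in result.retained)
        )
        vc = spatial.voxel_correlation(m)
        vc.to_csv(self.out / "voxel_correlation.tsv", sep="\t")
        for name in (
            "matrix_fully_quantified.tsv",
            "spatial_se.tsv",
            "spatial_retained.txt",
            "voxel_correlation.tsv",
        ):
            self.register("spatial", self.out / name)

    def stage_network(self):
        cfg = self.config
        m = getattr(self, "filtered_matrix", None)
        if m is None:
            m = spatial.fully_quantified(self.matrix)
        r = network.protein_correlation(m)
        adj = network.soft_adjacency(r, beta=cfg.beta, mode=cfg.mode)
        seed_protein = cfg.seed_protein
        if seed_protein is None:
            se = getattr(self, "se_result", spatial.se_filter(m, cfg.se_cutoff)).se
            seed_protein = str(se.idxmax())
        hood = network.seed_neighborhood(adj, seed_protein, k=cfg.top_k)
        inverse = network.inverse_partners(r, seed_protein, t=cfg.inverse_threshold)
        modules = network.detect_modules(adj, cut_height=cfg.cut_height)
        self.adjacency = adj
        self.seed_used = seed_protein
        self.modules = modules

        hood.neighbors.rename("adjacency").rename_axis("protein").to_csv(
            self.out / "seed_neighborhood.tsv", sep="\t"
        )
        inverse.rename("correlation").rename_axis("protein").to_csv(
            self.out / "inverse_partners.tsv", sep="\t"
        )
        modules.labels.rename("module").rename_axis("protein").to_csv(
            self.out / "modules.tsv", sep="\t"
        )
        nodes = {seed_protein, *hood.neighbors.index.astype(str)}
        edges = network.edge_list(adj, nodes, t=cfg.edge_threshold)
        with open(self.out / "seed_network_edges.tsv", "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for a, b, w in edges:
                fh.write(f"{a}\t{b}\t{w:.6g}\n")
        self._write_graphml(nodes, edges, self.out / "seed_network.graphml")
        for name in (
            "seed_neighborhood.tsv",
            "inverse_partners.tsv",
            "modules.tsv",
            "seed_network_edges.tsv",
            "seed_network.graphml",
        ):
            self.register("network", self.out / name)

    @staticmethod
    def _write_graphml(nodes, edges, path: Path):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(nodes, key=str))
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        nx.write_graphml(g, str(path))

    def stage_termmap(self):
        cfg = self.config
        m = getattr(self, "filtered_matrix", None)
        if m is None:
            m = spatial.fully_quantified(self.matrix)
        if self.terms:
            terms = dict(self.terms)
        else:
            terms = {}
            if getattr(self, "modules", None) is not None:
                labels = self.modules.labels
                terms.update(
                    {
                        f"module_{lab}": set(labels.index[labels == lab].astype(str))
                        for lab in sorted(labels.unique())
                        if lab != "0"
                    }
                )
            # the seed network itself is a term: its summed intensity maps the
            # process the seed protein tracks
            if getattr(self, "seed_used", None) is not None and hasattr(self, "adjacency"):
                hood = network.seed_neighborhood(self.adjacency, self.seed_used, k=cfg.top_k)
                terms["seed_network"] = {self.seed_used, *map(str, hood.neighbors.index)}
        universe = set(map(str, m.index))
        # enrich the seed network against independent annotation only (user
        # terms or detected modules), never against itself
        annotation = {t: members for t, members in terms.items() if t != "seed_network"}
        if annotation and "seed_network" in terms:
            query = terms["seed_network"] & universe
            table = termmaps.hypergeometric_enrichment(query, annotation, universe)
            table.to_csv(self.out / "enrichment.tsv", sep="\t", index=False)
            self.register("termmap", self.out / "enrichment.tsv")
        for term, members in sorted(terms.items()):
            if not members & universe:
                continue
            tmap = termmaps.term_summed_intensity(m, members, scale=cfg.term_scale, term=term)
            scaled = termmaps.heatmap_scale(tmap.values)
            svg = termmaps.render_svg(self.layout, scaled, title=term)
            safe = term.replace(":", "_").replace("/", "_")
            self.write_text("termmap", f"termmap_{safe}.svg", svg)
        seed_protein = getattr(self, "seed_used", None)
        if seed_protein in set(map(str, m.index)):
            row = m.loc[seed_protein]
            svg = termmaps.render_svg(
                self.layout, termmaps.heatmap_scale(row), title=seed_protein
            )
            self.write_text("termmap", f"heatmap_{seed_protein}.svg", svg)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the output manifest.

    The manifest (also written to ``manifest.json``) maps each stage to its
    output files and their sha256 hashes; a failed stage flags the manifest
    incomplete and the underlying error propagates after the partial
    manifest is written.
    """
    logging.basicConfig(level=config.log_level)
    run = _Run(config)
    run.prepare_inputs()
    stage_fn = {
        "qc": run.stage_qc,
        "rank": run.stage_rank,
        "spatial": run.stage_spatial,
        "network": run.stage_network,
        "termmap": run.stage_termmap,
    }
    try:
        for stage in STAGES:
            if stage in config.stages:
                log.info("running stage %s", stage)
                stage_fn[stage]()
    except Exception:
        run.manifest["incomplete"] = True
        raise
    finally:
        manifest_path = run.out / "manifest.json"
        manifest_path.write_text(json.dumps(run.manifest, indent=1, sort_keys=True) + "\n")
    return run.manifest
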