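"""End-to-end orchestration: structures → ensemble → screening → selectivity → plif.

Each stage reads and writes plain files (CSV/TSV/JSON) inside the run's
output directory, so any stage is independently re-runnable on its own
inputs.  A provenance manifest (config snapshot, input digests, package
version, per-stage row counts, timestamps) is written on every run,
success or failure.  All stochastic content lives in the seeded synthetic
generators, so re-running an identical config reproduces the data outputs
byte for byte; only the manifest's timestamps differ between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

import kinsel
from kinsel import ensemble as ens
from kinsel import plif as plifmod
from kinsel import screening as scr
from kinsel import selectivity as sel
from kinsel import structures as struc
from kinsel import synthetic as syn

logger = logging.getLogger(__name__)

STAGES = ("simulate", "sites", "cluster", "evaluate", "select", "rank", "plif")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config keys under {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class StructuresConfig:
    cutoff: float = 5.0
    input_pdbs: list[str] = field(default_factory=list)
    ligand_codes: dict[str, str] = field(default_factory=dict)


@dataclass
class EnsembleConfig:
    k: int | None = None            # None: silhouette over k_range
    k_range: list[int] = field(default_factory=lambda: [2, 8])
    population_threshold: float = 0.25
    cap: int = 3
    lbi_table: str | None = None
    lbi_threshold: float = 2.0
    mds_dims: int = 3


@dataclass
class ScreeningConfig:
    scores: str | None = None        # CSV; defaults to the simulated table
    activities: str | None = None    # CSV with pchembl / standard_value_nM
    components: list[str] = field(default_factory=lambda: ["total"])
    alpha: float = 20.0
    fractions: list[float] = field(default_factory=lambda: list(scr.DEFAULT_FRACTIONS))
    ef_fractions: list[float] = field(default_factory=lambda: [0.01])
    auc_min: float = 0.70


@dataclass
class SelectivityConfig:
    kinase_a: str = "kinaseA"
    kinase_b: str = "kinaseB"
    consensus: str = sel.MEAN_RANK
    top_fraction: float = 0.05
    rr_cutoff: float = 0.0
    separation_margin: float = 0.05
    descriptors: str | None = None
    component: str = "total"


@dataclass
class PlifConfig:
    position_map: str | None = None
    criteria: dict = field(default_factory=dict)
    stable_rmsd: float = 2.0


@dataclass
class SyntheticConfig:
    ensemble: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    complex: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run; unknown keys are rejected."""

    output_dir: str = "kinsel_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    structures: StructuresConfig = field(default_factory=StructuresConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    selectivity: SelectivityConfig = field(default_factory=SelectivityConfig)
    plif: PlifConfig = field(default_factory=PlifConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}; valid stages are {list(STAGES)}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "structures": StructuresConfig,
            "ensemble": EnsembleConfig,
            "screening": ScreeningConfig,
            "selectivity": SelectivityConfig,
            "plif": PlifConfig,
            "synthetic": SyntheticConfig,
        }
        parsed = {}
        for key, section_cls in sections.items():
            if key in data:
                section = data.pop(key)
                if not isinstance(section, dict):
                    raise ConfigError(f"config section {key} must be a mapping")
                parsed[key] = _from_mapping(section_cls, section, key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data, **parsed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(data)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    config: dict
    version: str
    started: str
    stages: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    status: str = "running"
    failed_stage: str | None = None
    finished: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


class PipelineRun:
    """Executes the enabled stages in order and records provenance."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = Manifest(
            config=config.snapshot(), version=kinsel.__version__, started=_now()
        )

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> dict:
        cfg = self.config.synthetic
        seed = self.config.seed
        espec = syn.EnsembleSpec(**{"seed": seed, **cfg.ensemble})
        structures, partition = syn.gen_conformer_ensemble(espec)
        pdb_dir = self.out / "synthetic_structures"
        pdb_dir.mkdir(exist_ok=True)
        for s in structures:
            struc.write_structure(s, pdb_dir / f"{s.structure_id}.pdb")
        pd.DataFrame(
            sorted(partition.items()), columns=["structure_id", "cluster"]
        ).to_csv(self.out / "truth_partition.csv", index=False)

        sspec = syn.ScreenSpec(**{"seed": seed + 1, **cfg.screen})
        scores, truth = syn.gen_screen_table(sspec)
        scores.to_csv(self.out / "synthetic_scores.csv", index=False, float_format="%.6f")
        truth.to_csv(self.out / "truth_ligands.csv", index=False)

        cspec = syn.ComplexSpec(
            **{
                "seed": seed + 2,
                "planted": [tuple(b) for b in cfg.complex.get("planted", [
                    ["hinge.46", plifmod.HBOND_ACCEPTOR],
                    ["hinge.48", plifmod.HBOND_DONOR],
                    ["aD.55", plifmod.HYDROPHOBIC],
                ])],
                "n_decoys": cfg.complex.get("n_decoys", 20),
            }
        )
        cx = syn.gen_complex(cspec)
        struc.write_structure(cx.protein, self.out / "synthetic_complex_protein.pdb")
        cx.position_map.to_csv(self.out / "synthetic_position_map.csv")
        pd.DataFrame(
            sorted(cx.planted_bits), columns=["position", "interaction"]
        ).to_csv(self.out / "truth_planted_bits.csv", index=False)
        self._complex = cx
        self._structures = structures
        return {
            "structures": len(structures),
            "score_rows": len(scores),
            "planted_bits": len(cx.planted_bits),
        }

    def _load_structures(self) -> list[struc.StructureRecord]:
        if getattr(self, "_structures", None) is not None:
            return self._structures
        cfg = self.config.structures
        paths = [Path(p) for p in cfg.input_pdbs]
        if not paths:
            pdb_dir = self.out / "synthetic_structures"
            paths = sorted(pdb_dir.glob("*.pdb"))
        if not paths:
            raise ConfigError("sites stage: no input PDB files configured or simulated")
        records = []
        for p in paths:
            records.extend(struc.read_structures(p, cfg.ligand_codes or None))
        return records

    def stage_sites(self) -> dict:
        cfg = self.config.structures
        structures = self._load_structures()
        sites = [struc.extract_binding_site(s, cfg.cutoff) for s in structures]
        struc.write_binding_sites(sites, self.out / "binding_sites.json")
        site = set().union(*(s.member_residue_ids for s in sites))
        if not site:
            logger.warning("consensus binding site empty; using all residues")
            site = {a.residue_id for s in structures for a in s.protein_heavy_atoms()}
        aligned, ref_id = struc.superpose_ensemble(structures, site)
        D = struc.pairwise_rmsd_matrix(aligned, site)
        D.to_tsv(self.out / "site_rmsd_matrix.tsv")
        self._aligned = aligned
        return {
            "structures": len(structures),
            "site_residues": len(site),
            "reference": ref_id,
        }

    def stage_cluster(self) -> dict:
        cfg = self.config.ensemble
        D = struc.DistanceMatrix.from_tsv(self.out / "site_rmsd_matrix.tsv")
        k = cfg.k if cfg.k is not None else ens.choose_k(D, tuple(cfg.k_range))
        model = ens.complete_linkage_cluster(D, k)
        model.to_frame().to_csv(self.out / "cluster_assignments.csv", index=False)
        reps = ens.select_representatives(
            D, model, population_threshold=cfg.population_threshold, cap=cfg.cap
        )
        if cfg.lbi_table:
            lbi = ens.load_lbi_table(cfg.lbi_table, cfg.lbi_threshold)
            reps = ens.apply_lbi_filter(reps, lbi, D, model)
        reps.to_json(self.out / "representatives.json")
        coords = ens.mds_project(D, cfg.mds_dims)
        coords.to_csv(self.out / "mds_coordinates.csv", float_format="%.6f")
        return {"k": k, "representatives": len(reps.all_ids())}

    def _load_scores(self) -> pd.DataFrame:
        path = self.config.screening.scores or self.out / "synthetic_scores.csv"
        scores = pd.read_csv(path)
        return scr.best_poses(scores)

    def _load_labels(self) -> pd.DataFrame:
        cfg = self.config.screening
        if cfg.activities:
            return scr.classify_table(pd.read_csv(cfg.activities))[["ligand_id", "label"]]
        truth = pd.read_csv(self.out / "truth_ligands.csv")
        return truth[["ligand_id", "label"]]

    def stage_evaluate(self) -> dict:
        cfg = self.config.screening
        scores = self._load_scores().merge(self._load_labels(), on="ligand_id")
        reports = []
        for kinase, grp in scores.groupby("kinase_id", sort=True):
            reports.extend(
                scr.evaluate_screen(
                    grp, components=tuple(cfg.components), alpha=cfg.alpha,
                    fractions=tuple(cfg.fractions),
                    ef_fractions=tuple(cfg.ef_fractions),
                )
            )
        scr.write_reports(reports, self.out / "metrics_reports.json")
        agg = scr.aggregate_conformers(reports)
        agg["per_conformer"].to_csv(
            self.out / "per_conformer_metrics.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        self._reports = reports
        return {"reports": len(reports)}

    def stage_select(self) -> dict:
        cfg = self.config.screening
        reports = getattr(self, "_reports", None)
        if reports is None:
            report_path = self.out / "metrics_reports.json"
            if not report_path.exists():
                raise ConfigError(
                    "select stage: run the evaluate stage first "
                    "(metrics_reports.json not found)"
                )
            reports = scr.read_reports(report_path)
        selected = scr.select_conformers(
            reports, auc_min=cfg.auc_min, ef_fraction=cfg.ef_fractions[0]
        )
        (self.out / "selected_conformers.json").write_text(
            json.dumps(selected, indent=2) + "\n"
        )
        self._selected = selected
        return {"selected": len(selected)}

    def stage_rank(self) -> dict:
        cfg = self.config.selectivity
        scores = self._load_scores()
        selected = getattr(self, "_selected", None)
        if selected is None and (self.out / "selected_conformers.json").exists():
            selected = json.loads((self.out / "selected_conformers.json").read_text())
        ranks = {}
        for role, kinase in (("A", cfg.kinase_a), ("B", cfg.kinase_b)):
            slab = scores[scores["kinase_id"] == kinase]
            if slab.empty:
                raise ConfigError(f"no score rows for kinase {kinase}")
            confs = None
            if selected:
                confs = [c for c in selected if c in set(slab["conformer_id"])]
                confs = confs or None
            ranks[role] = sel.normalize_ranks(
                slab, conformers=confs, consensus=cfg.consensus,
                component=cfg.component,
            )
        table = sel.selectivity_table(ranks["A"], ranks["B"])
        table.to_csv(self.out / "selectivity.csv", index=False, float_format="%.6f")
        report = sel.concordance(ranks["A"], ranks["B"])
        (self.out / "concordance.json").write_text(
            json.dumps(report.as_dict(), indent=2) + "\n"
        )
        descriptors = (
            pd.read_csv(cfg.descriptors) if cfg.descriptors else None
        )
        hits = sel.prioritize_hits(
            ranks["A"], ranks["B"], top_fraction=cfg.top_fraction,
            rr_cutoff=cfg.rr_cutoff, separation_margin=cfg.separation_margin,
            descriptors=descriptors,
        )
        prov = hits.attrs["provenance"]
        for key, value in prov.items():
            hits[key] = value
        hits.to_csv(self.out / "hit_list.csv", index=False, float_format="%.6f")
        return {"ligands": len(table), "hits": len(hits)}

    def stage_plif(self) -> dict:
        cfg = self.config.plif
        cx = getattr(self, "_complex", None)
        if cx is None:
            raise ConfigError(
                "plif stage requires the simulate stage's synthetic complex"
            )
        criteria = plifmod.InteractionCriteria(**cfg.criteria)
        fp = plifmod.detect_interactions(cx.pose, cx.protein, cx.position_map, criteria)
        rows = pd.DataFrame(sorted(fp.bits), columns=["position", "interaction"])
        rows.to_csv(self.out / "fingerprint.csv", index=False)
        result = {
            "bits": len(fp.bits),
            "hinge_motif": plifmod.hinge_motif(fp),
            "matches_planted": fp.bits == cx.planted_bits,
        }
        (self.out / "plif_summary.json").write_text(json.dumps(result, indent=2) + "\n")
        return result

    # -- driver -----------------------------------------------------------

    def run(self) -> Manifest:
        handlers = {
            "simulate": self.stage_simulate,
            "sites": self.stage_sites,
            "cluster": self.stage_cluster,
            "evaluate": self.stage_evaluate,
            "select": self.stage_select,
            "rank": self.stage_rank,
            "plif": self.stage_plif,
        }
        for path in self.config.structures.input_pdbs:
            p = Path(path)
            if p.exists():
                self.manifest.inputs[str(p)] = _sha256(p)
        try:
            for stage in STAGES:
                if stage not in self.config.stages:
                    continue
                logger.info("stage %s: starting", stage)
                info = handlers[stage]()
                self.manifest.stages[stage] = info
                logger.info("stage %s: %s", stage, info)
            self.manifest.status = "ok"
        except Exception as exc:
            self.manifest.status = "failed"
            self.manifest.failed_stage = next(
                (s for s in self.config.stages if s not in self.manifest.stages), None
            )
            self.manifest.finished = _now()
            self.manifest.write(self.out / "manifest.json")
            raise
        self.manifest.finished = _now()
        self.manifest.write(self.out / "manifest.json")
        return self.manifest


def run(config: RunConfig) -> Manifest:
    """Execute the enabled pipeline stages; see :class:`PipelineRun`."""
    return PipelineRun(config).run()
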