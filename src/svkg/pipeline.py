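"""End-to-end orchestration: panel → genomes → index → simulate → featurize
→ train → genotype → evaluate, from one YAML config.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so a rerun with the same config reproduces all
non-timing outputs byte-identically.  A manifest JSON records, per stage,
the output files with content hashes and wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dataset import plan_dataset, simulate_dataset, simulate_sample_genome
from .evaluation import confusion_and_accuracy
from .genotyper import TrainingConfig, predict, save_model, train
from .kmers import build_kmer_index, save_index
from .readsim import ReadSimParams, simulate_reads, write_fastq
from .region import BlueprintError, BoxSpec, CassetteSpec, RegionBlueprint, save_panel, generate_haplotype_panel
from .variants import ALL_GENOTYPES, DEFAULT_SVS, SVDefinition, build_genotype_panel
from .kmers import KmerFeatureVector

__all__ = ["RunConfig", "ValidationReport", "validate_config", "run_pipeline", "derive_seed"]

STAGES = (
    "panel",
    "genomes",
    "index",
    "simulate",
    "featurize",
    "train",
    "genotype",
    "evaluate",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from master seed + name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "svkg_run"
    master_seed: int = 42
    blueprint: RegionBlueprint = field(default_factory=RegionBlueprint)
    svs: dict[str, SVDefinition] = field(default_factory=lambda: dict(DEFAULT_SVS))
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    k: int = 21
    stride: int = 30
    training: TrainingConfig = field(default_factory=TrainingConfig)
    coverage: float = 30.0
    n_train: int = 240
    n_heldout: int = 100
    n_example_fastq: int = 1
    normalize_mode: str = "raw"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        bp_raw = raw.get("blueprint", {})
        if bp_raw:
            boxes = bp_raw.get("box_specs")
            cassette = bp_raw.get("cassette")
            bp_kwargs = {
                key: bp_raw[key]
                for key in ("region_length", "snp_rate", "n_haplotypes", "seed")
                if key in bp_raw
            }
            if cassette:
                bp_kwargs["cassette"] = CassetteSpec(**cassette)
            if boxes:
                bp_kwargs["box_specs"] = tuple(
                    BoxSpec(
                        name=b["name"],
                        length=b["length"],
                        positions=tuple(b["positions"]),
                        divergence=b.get("divergence", 0.0),
                    )
                    for b in boxes
                )
            cfg = dataclasses.replace(cfg, blueprint=RegionBlueprint(**bp_kwargs))
        if "svs" in raw:
            svs = {}
            for entry in raw["svs"]:
                sv = SVDefinition(
                    name=entry["name"],
                    box_pair=entry["box_pair"],
                    breakpoint_offset=entry.get("breakpoint_offset"),
                )
                svs[sv.name] = sv
            cfg = dataclasses.replace(cfg, svs=svs)
        if "readsim" in raw:
            cfg = dataclasses.replace(cfg, read_params=ReadSimParams(**raw["readsim"]))
        if "kmer" in raw:
            cfg = dataclasses.replace(
                cfg,
                k=raw["kmer"].get("k", cfg.k),
                stride=raw["kmer"].get("stride", cfg.stride),
            )
        if "training" in raw:
            tr = dict(raw["training"])
            if "grid" in tr:
                tr["grid"] = tuple(dict(g) for g in tr["grid"])
            cfg = dataclasses.replace(cfg, training=TrainingConfig(**tr))
        for key in (
            "out_dir", "master_seed", "coverage", "n_train", "n_heldout",
            "n_example_fastq", "normalize_mode",
        ):
            if key in raw:
                cfg = dataclasses.replace(cfg, **{key: raw[key]})
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.errors


def validate_run_config(cfg: RunConfig) -> ValidationReport:
    report = ValidationReport()
    try:
        cfg.blueprint.validate()
    except BlueprintError as exc:
        report.errors.append(f"blueprint: {exc}")
    for required in ("del3.7", "del4.2"):
        if required not in cfg.svs:
            report.errors.append(f"svs: missing SV definition {required!r}")
    box_names = {b.name for b in cfg.blueprint.box_specs}
    for sv in cfg.svs.values():
        if sv.box_pair not in box_names:
            report.errors.append(
                f"svs.{sv.name}: box pair {sv.box_pair!r} not in blueprint box_specs"
            )
    try:
        cfg.read_params.validate()
    except ValueError as exc:
        report.errors.append(f"readsim.{exc}" if ":" not in str(exc) else f"readsim: {exc}")
    if cfg.read_params.coverage <= 0:
        pass  # already reported by validate()
    if cfg.k < 11:
        report.errors.append(f"kmer.k: must be >= 11, got {cfg.k}")
    if cfg.stride < 1:
        report.errors.append(f"kmer.stride: must be >= 1, got {cfg.stride}")
    try:
        cfg.training.validate()
    except ValueError as exc:
        report.errors.append(f"training: {exc}")
    if cfg.coverage <= 0:
        report.errors.append(f"readsim.coverage: must be > 0, got {cfg.coverage}")
    if cfg.n_train < 6 * cfg.training.n_folds:
        report.errors.append(
            f"n_train: need at least {6 * cfg.training.n_folds} samples so every "
            f"class appears in each of {cfg.training.n_folds} folds, got {cfg.n_train}"
        )
    if cfg.n_heldout < 1:
        report.errors.append(f"n_heldout: must be >= 1, got {cfg.n_heldout}")
    if cfg.normalize_mode not in ("raw", "per-haploid-copy"):
        report.errors.append(f"normalize_mode: unknown mode {cfg.normalize_mode!r}")
    return report


def validate_config(path) -> ValidationReport:
    """Validate a YAML run config; parse failures become errors in the report."""
    try:
        cfg = RunConfig.from_yaml(path)
    except Exception as exc:  # malformed YAML or bad field structure
        return ValidationReport(errors=[f"config parse failure: {exc}"])
    return validate_run_config(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_plan(path: Path, plan, panel) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\tmaternal_template\tpaternal_template\tread_seed\n")
        for i, (label, mi, pi, read_seed) in enumerate(plan):
            fh.write(f"s{i:04d}\t{label}\t{panel[mi].id}\t{panel[pi].id}\t{read_seed}\n")


def _write_features(path: Path, dataset) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\tnormalizer\t" + "\t".join(
            f"f{i}" for i in range(dataset.X.shape[1])
        ) + "\n")
        for i in range(dataset.n_samples):
            counts = "\t".join(f"{v:g}" for v in dataset.X[i])
            norm = dataset.normalizers[i] if dataset.normalizers is not None else 1.0
            fh.write(f"{dataset.sample_ids[i]}\t{dataset.labels[i]}\t{norm:g}\t{counts}\n")


def run_pipeline(config: RunConfig, progress: bool = False) -> Path:
    """Run all stages; returns the run directory.

    Fails fast on an invalid config.  Any stage failure raises with the
    stage name attached.
    """
    report = validate_run_config(config)
    if not report.valid:
        raise ValueError("invalid run config:\n" + "\n".join(report.errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"svkg_version": __version__, "master_seed": config.master_seed, "stages": []}
    state: dict = {}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "files": [
                    {"path": str(f.relative_to(out)), "sha256": _sha256(f)} for f in files
                ],
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )

    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        record(stage, files, t0)
        if progress:
            print(f"[svkg] stage {stage} done ({manifest['stages'][-1]['seconds']}s)")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return out


# --- stage implementations -------------------------------------------------


def _stage_panel(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    blueprint = dataclasses.replace(
        cfg.blueprint, seed=derive_seed(cfg.master_seed, "panel")
    )
    panel = generate_haplotype_panel(blueprint)
    state["panel"] = panel
    fasta, boxes = out / "panel.fasta", out / "panel_boxes.tsv"
    save_panel(panel, fasta, boxes)
    return [fasta, boxes]


def _stage_genomes(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    genomes = build_genotype_panel(state["panel"], cfg.svs)
    state["genomes"] = genomes
    path = out / "genomes.tsv"
    with open(path, "w") as fh:
        fh.write("genome_id\tlabel\tmaternal_template\tpaternal_template\t"
                 "maternal_length\tpaternal_length\n")
        for g in genomes:
            fh.write(
                f"{g.id}\t{g.label}\t{g.template_ids[0]}\t{g.template_ids[1]}\t"
                f"{len(g.maternal)}\t{len(g.paternal)}\n"
            )
    return [path]


def _stage_index(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    index = build_kmer_index(state["panel"], k=cfg.k, stride=cfg.stride, svs=cfg.svs)
    state["index"] = index
    tsv, js = out / "index.tsv", out / "index.json"
    save_index(index, tsv, js)
    return [tsv, js]


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    panel = state["panel"]
    train_seed = derive_seed(cfg.master_seed, "simulate-train")
    heldout_seed = derive_seed(cfg.master_seed, "simulate-heldout")
    state["train_seed"], state["heldout_seed"] = train_seed, heldout_seed
    train_plan = plan_dataset(len(panel), cfg.n_train, train_seed)
    heldout_plan = plan_dataset(len(panel), cfg.n_heldout, heldout_seed)
    files = [out / "train_samples.tsv", out / "heldout_samples.tsv"]
    _write_plan(files[0], train_plan, panel)
    _write_plan(files[1], heldout_plan, panel)
    for i, (label, mi, pi, read_seed) in enumerate(heldout_plan[: cfg.n_example_fastq]):
        genome = simulate_sample_genome(panel, label, mi, pi, cfg.svs)
        params = dataclasses.replace(cfg.read_params, coverage=cfg.coverage, seed=read_seed)
        reads = simulate_reads(genome, params)
        r1, r2 = out / f"example_{i}_R1.fastq", out / f"example_{i}_R2.fastq"
        write_fastq(reads, r1, r2)
        files += [r1, r2]
    return files


def _stage_featurize(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    panel, index = state["panel"], state["index"]
    common = dict(
        read_params=cfg.read_params, svs=cfg.svs, normalize_mode=cfg.normalize_mode
    )
    state["train_set"] = simulate_dataset(
        panel, index, cfg.n_train, cfg.coverage, state["train_seed"],
        id_prefix="train_", **common,
    )
    state["heldout_set"] = simulate_dataset(
        panel, index, cfg.n_heldout, cfg.coverage, state["heldout_seed"],
        id_prefix="test_", **common,
    )
    files = [out / "train_features.tsv", out / "heldout_features.tsv"]
    _write_features(files[0], state["train_set"])
    _write_features(files[1], state["heldout_set"])
    return files


def _stage_train(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    training = dataclasses.replace(cfg.training, seed=derive_seed(cfg.master_seed, "train"))
    model = train(state["train_set"], config=training)
    state["model"] = model
    path = out / "model.svkg"
    save_model(model, path)
    return [path, Path(str(path) + ".json")]


def _stage_genotype(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    model, heldout = state["model"], state["heldout_set"]
    path = out / "genotypes.tsv"
    predictions = []
    with open(path, "w") as fh:
        header = ["sample_id", "genotype"] + [str(g) for g in ALL_GENOTYPES] + ["flag"]
        fh.write("\t".join(header) + "\n")
        for i in range(heldout.n_samples):
            vec = KmerFeatureVector(
                index_hash=heldout.index_hash,
                counts=heldout.X[i],
                sample_id=heldout.sample_ids[i],
            )
            label, probs, flag = predict(model, vec)
            predictions.append(label)
            row = [heldout.sample_ids[i], str(label)]
            row += [f"{probs[g]:.6f}" for g in ALL_GENOTYPES]
            row.append(flag)
            fh.write("\t".join(row) + "\n")
    state["predictions"] = predictions
    return [path]


def _stage_evaluate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    heldout = state["heldout_set"]
    matrix = confusion_and_accuracy(
        heldout.labels, state["predictions"], class_order=list(ALL_GENOTYPES)
    )
    conf = out / "confusion.tsv"
    matrix.to_dataframe().to_csv(conf, sep="\t")
    rep = out / "report.txt"
    with open(rep, "w") as fh:
        fh.write(
            f"held-out samples: {matrix.total}\n"
            f"correct: {matrix.n_correct}\n"
            f"accuracy: {matrix.accuracy:.4f}\n"
        )
        if matrix.total > matrix.n_correct:
            t, p, c = matrix.modal_confusion()
            fh.write(f"modal confusion: truth {t} predicted {p} ({c} samples)\n")
    return [conf, rep]


_STAGE_FUNCS = {
    "panel": _stage_panel,
    "genomes": _stage_genomes,
    "index": _stage_index,
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "genotype": _stage_genotype,
    "evaluate": _stage_evaluate,
}
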