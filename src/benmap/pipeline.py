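"""End-to-end reproducible runs: generation -> entropy -> statistics -> files.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes it
and writes, under the output directory:

* ``config_resolved.yaml`` — the fully-resolved configuration (the
  reproducibility record),
* ``per_image_ben.csv`` and ``per_subject_ben.csv``,
* ``group_comparison.csv`` / ``group_comparison.json`` and ``summary.txt``,
* ``labels/*.png`` — indexed label maps for segmentation audit,
* ``run.log``.

Synthetic mode additionally writes the generated cohort (PNG images plus
``subjects.csv``) so the same run can later be re-analysed in from-images
mode.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .colors import DEFAULT_PALETTE, ColorPalette
from .model import BrainEntropyModel, BrainEntropyResults
from .segmentation import segment_and_clean
from .stats import Coding, DEFAULT_CODING
from .synthetic import Cohort, CohortGenConfig, MapGenConfig, generate_cohort

logger = logging.getLogger("benmap")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` is either ``"synthetic"`` (generate a cohort, then analyse it)
    or ``"from-images"`` (read ``table_path`` + rasters under ``image_root``).
    """

    mode: str = "synthetic"
    outdir: str | Path = "benmap_run"
    seed: int = 0
    table_path: str | Path | None = None
    image_root: str | Path | None = None
    palette_path: str | Path | None = None
    normalize: bool = True
    equal_var: bool = True
    write_label_maps: bool = True
    log_level: str = "INFO"
    cohort: CohortGenConfig = field(default_factory=CohortGenConfig)
    map_config: MapGenConfig = field(default_factory=MapGenConfig)
    coding: Coding = field(default_factory=lambda: DEFAULT_CODING)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "from-images"):
            raise ValueError(f"mode must be 'synthetic' or 'from-images', got {self.mode!r}")

    def resolved_palette(self) -> ColorPalette:
        if self.palette_path is not None:
            return ColorPalette.from_csv(self.palette_path)
        return DEFAULT_PALETTE

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "outdir": str(self.outdir),
            "seed": self.seed,
            "table_path": str(self.table_path) if self.table_path else None,
            "image_root": str(self.image_root) if self.image_root else None,
            "palette_path": str(self.palette_path) if self.palette_path else None,
            "normalize": self.normalize,
            "equal_var": self.equal_var,
            "write_label_maps": self.write_label_maps,
            "log_level": self.log_level,
            "coding": {
                "gender": dict(self.coding.gender_codes),
                "group": dict(self.coding.group_codes),
            },
        }
        if self.mode == "synthetic":
            d["cohort"] = {
                "images_per_subject": self.cohort.images_per_subject,
                "seed": self.cohort.seed,
                "use_recruitment_counts": self.cohort.use_recruitment_counts,
                "groups": [dataclasses.asdict(g) for g in self.cohort.groups],
            }
            d["map_config"] = dataclasses.asdict(self.map_config)
        return d


@dataclass
class RunReport:
    """What a pipeline run produced and where it was written."""

    outdir: Path
    results: BrainEntropyResults
    paths: dict[str, Path]
    excluded: list[tuple[str, str]]


def _configure_logging(outdir: Path, level: str) -> logging.FileHandler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one run; returns the report and writes all outputs.

    Raises ``FileNotFoundError`` (naming the missing file) when inputs are
    absent in from-images mode.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _configure_logging(outdir, config.log_level)
    try:
        palette = config.resolved_palette()
        with open(outdir / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

        if config.mode == "synthetic":
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            map_cfg = config.map_config
            logger.info("generating synthetic cohort (seed=%d)", config.seed)
            cohort: Cohort = generate_cohort(cohort_cfg, map_cfg, palette)
            cohort.write(outdir / "cohort")
            model = BrainEntropyModel.from_cohort(
                cohort, palette=palette, coding=config.coding,
                normalize=config.normalize,
            )
        else:
            if config.table_path is None:
                raise FileNotFoundError("from-images mode requires table_path")
            model = BrainEntropyModel.from_csv(
                config.table_path, image_root=config.image_root,
                palette=palette, coding=config.coding,
                normalize=config.normalize,
            )

        results = model.fit(equal_var=config.equal_var)

        for sid, reason in results.excluded:
            logger.warning("subject %s excluded: %s", sid, reason)
        for sid in results.per_subject["subject_id"]:
            n = results.per_image.loc[
                results.per_image["subject_id"] == sid, "n_pixels"
            ].sum()
            logger.info("subject %s: %d retained pixels", sid, int(n))

        paths = {
            "config": outdir / "config_resolved.yaml",
            "per_image": outdir / "per_image_ben.csv",
            "per_subject": outdir / "per_subject_ben.csv",
            "comparison_csv": outdir / "group_comparison.csv",
            "comparison_json": outdir / "group_comparison.json",
            "summary": outdir / "summary.txt",
        }
        results.per_image.to_csv(paths["per_image"], index=False,
                                 float_format="%.10g")
        results.per_subject.to_csv(paths["per_subject"], index=False,
                                   float_format="%.10g")
        results.group_comparison.to_frame().to_csv(paths["comparison_csv"],
                                                   index=False,
                                                   float_format="%.10g")
        report = results.group_comparison.to_dict()
        report["excluded_subjects"] = [
            {"subject_id": sid, "reason": reason}
            for sid, reason in results.excluded
        ]
        with open(paths["comparison_json"], "w") as fh:
            json.dump(report, fh, indent=2)
        paths["summary"].write_text(results.summary() + "\n")

        if config.write_label_maps:
            label_dir = outdir / "labels"
            label_dir.mkdir(exist_ok=True)
            for sid, imgs in model.images.items():
                for k, img in enumerate(imgs, start=1):
                    seg = segment_and_clean(img, palette)
                    seg.save_label_map(label_dir / f"{sid}_img{k}_labels.png")
            paths["labels"] = label_dir

        logger.info("run complete: %s", outdir)
        return RunReport(outdir=outdir, results=results, paths=paths,
                         excluded=results.excluded)
    finally:
        logger.removeHandler(handler)
        handler.close()
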