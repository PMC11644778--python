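"""End-to-end survey analysis pipeline.

One call runs: ingest (or generate) a survey -> descriptive summaries ->
background estimation -> contamination/risk indices -> correlation and PCA
screens -> delimited-text reports, GeoJSON export and a run manifest.
Every stage writes the standard delimited forms so stages compose; a fixed
seed makes the whole run reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .background import BackgroundConfig, estimate_background
from .descriptives import summaries_to_frame, summary_table
from .indices import assess_sites, reports_to_frame, reports_to_long_frame
from .multivariate import mann_whitney_compare, pca_summary, spearman_holm
from .registry import PLI_ELEMENTS
from .simulate import GeneratorConfig, default_georgia_like_config, generate_survey
from .survey import (
    ToxicResponseTable,
    read_survey,
    write_geojson,
    write_survey,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be set; when
    neither is, a default synthetic survey is generated from ``seed``.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    pli_elements: tuple[str, ...] = tuple(PLI_ELEMENTS)
    trf_overrides: dict[str, float] = field(default_factory=dict)
    out_dir: str = "mossrisk_out"
    seed: int = 0
    write_geojson_file: bool = True
    by_species: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "generator" in data and data["generator"] is not None:
            data["generator"] = GeneratorConfig.from_dict(data["generator"])
        if "background" in data and data["background"] is not None:
            data["background"] = BackgroundConfig(**data["background"])
        if "pli_elements" in data:
            data["pli_elements"] = tuple(data["pli_elements"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "generator": self.generator.to_dict() if self.generator else None,
            "background": dataclasses.asdict(self.background),
            "pli_elements": list(self.pli_elements),
            "trf_overrides": dict(self.trf_overrides),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "write_geojson_file": self.write_geojson_file,
            "by_species": self.by_species,
        }


def _trf(config: PipelineConfig) -> ToxicResponseTable:
    if not config.trf_overrides:
        return ToxicResponseTable()
    from .registry import DEFAULT_TRF

    merged = dict(DEFAULT_TRF)
    merged.update(config.trf_overrides)
    return ToxicResponseTable(merged)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the in-memory results and written paths.

    Outputs land in ``config.out_dir``. Any stage error aborts the run
    with a stage-named ``PipelineError`` and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    stage = "ingest"
    try:
        if config.input_path is not None:
            matrix = read_survey(config.input_path)
            truth = None
        else:
            generator = config.generator or default_georgia_like_config(config.seed)
            matrix, truth = generate_survey(generator)
            emit("survey.csv", lambda p: write_survey(matrix, p))

        stage = "descriptives"
        summaries = summary_table(matrix, by_species=config.by_species)
        emit(
            "summary.csv",
            lambda p: summaries_to_frame(summaries).to_csv(p, index=False),
        )

        stage = "background"
        bg_result = estimate_background(matrix, config.background)
        emit("background.csv", lambda p: bg_result.to_frame().to_csv(p, index=False))

        stage = "indices"
        reports = assess_sites(
            matrix, bg_result.table, _trf(config), config.pli_elements
        )
        emit(
            "site_indices.csv",
            lambda p: reports_to_frame(reports).to_csv(p, index=False),
        )
        emit(
            "site_indices_long.csv",
            lambda p: reports_to_long_frame(reports).to_csv(p, index=False),
        )
        if config.write_geojson_file:
            emit("sites.geojson", lambda p: write_geojson(reports, matrix.sites, p))

        stage = "multivariate"
        correlation = spearman_holm(matrix)
        emit("spearman_rho.csv", lambda p: correlation.rho_frame().to_csv(p))
        emit(
            "spearman_p_adjusted.csv",
            lambda p: correlation.p_adjusted_frame().to_csv(p),
        )
        pca = pca_summary(matrix)
        emit("pca_loadings.csv", lambda p: pca.loadings.to_csv(p))
        emit(
            "pca_variance.csv",
            lambda p: Path(p).write_text(
                "component,variance_percent\n"
                + "\n".join(
                    f"PC{i + 1},{v!r}" for i, v in enumerate(pca.variance_percent)
                )
                + "\n",
                encoding="utf-8",
            ),
        )

        stage = "manifest"
        manifest = {
            "mossrisk_version": __version__,
            "seed": config.seed,
            "n_sites": matrix.n_sites,
            "elements": list(matrix.elements),
            "config": config.to_dict(),
            "outputs": [p.name for p in written],
        }
        emit(
            "manifest.json",
            lambda p: Path(p).write_text(
                json.dumps(manifest, indent=2), encoding="utf-8"
            ),
        )
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    logger.info("pipeline complete: %d outputs in %s", len(written), out_dir)
    return {
        "matrix": matrix,
        "truth": truth,
        "summaries": summaries,
        "background": bg_result,
        "reports": reports,
        "correlation": correlation,
        "pca": pca,
        "paths": written,
    }


def compare_surveys(
    path_a: str | Path,
    path_b: str | Path,
    background_config: BackgroundConfig | None = None,
    alpha: float = 0.05,
):
    """Compare two surveys element-wise.

    Runs the two-sided Mann-Whitney test on raw concentrations and, with
    each survey's *own* estimated background, on contamination factors
    (the CF comparison is the one robust to between-survey baseline
    shifts). Returns a DataFrame with one row per shared element.
    """
    import pandas as pd

    a = read_survey(path_a)
    b = read_survey(path_b)
    shared = [e for e in a.elements if e in set(b.elements)]
    if not shared:
        raise ValueError("surveys share no elements")
    config = background_config or BackgroundConfig()
    bg_a = estimate_background(a, config).table
    bg_b = estimate_background(b, config).table

    conc = mann_whitney_compare(a, b, alpha=alpha).table.set_index("element")
    cf_a = a.to_frame()[shared] / pd.Series({e: bg_a[e] for e in shared})
    cf_b = b.to_frame()[shared] / pd.Series({e: bg_b[e] for e in shared})
    cf = mann_whitney_compare(cf_a, cf_b, alpha=alpha).table.set_index("element")

    rows = []
    for element in shared:
        rows.append(
            {
                "element": element,
                "n_a": a.n_sites,
                "n_b": b.n_sites,
                "u_conc": conc.loc[element, "u"],
                "p_conc": conc.loc[element, "p"],
                "significant_conc": bool(conc.loc[element, "significant"]),
                "median_cf_a": float(cf_a[element].median()),
                "median_cf_b": float(cf_b[element].median()),
                "u_cf": cf.loc[element, "u"],
                "p_cf": cf.loc[element, "p"],
                "significant_cf": bool(cf.loc[element, "significant"]),
            }
        )
    return pd.DataFrame(rows)
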