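"""End-to-end analysis on the bundled dataset: metrics grid + concordance.

``run_paper_analysis`` composes the stages into the study's composite result:
the four-model performance grid, the ProtReact-Cys vs DPRA-mean concordance
report with per-domain tallies, and a manifest (package version, seed,
config hash) making two runs with the same configuration byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import BUILTIN_MODELS, DPRA_MEAN, PROTREACT_CYS, PredictionModelConfig
from .concordance import compare_models
from .dataset import load_dataset, load_domains
from .evaluate import table3_grid

__all__ = ["PipelineConfig", "load_config", "run_paper_analysis"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end analysis."""

    dataset_path: str | None = None       # None -> bundled table
    domains_path: str | None = None       # None -> bundled synthetic annotation
    model_a: str = "protreact:protreact_cys"
    model_b: str = "dpra:dpra_mean"
    nc_max_pct: float = 10.0
    pc_min_pct: float = 50.0
    seed: int = 0

    def resolve_model(self, spec: str) -> tuple[str, PredictionModelConfig]:
        """Parse 'assay:model_name' against the built-in model registry."""
        assay, _, name = spec.partition(":")
        if assay not in ("protreact", "dpra"):
            raise ValueError(f"unknown assay in model spec {spec!r}")
        if name not in BUILTIN_MODELS:
            raise ValueError(f"unknown model {name!r}; choose from {sorted(BUILTIN_MODELS)}")
        return assay, BUILTIN_MODELS[name]


def load_config(path) -> PipelineConfig:
    """Load a TOML pipeline configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_paper_analysis(
    config: PipelineConfig | None = None, out_dir: str | Path | None = None
) -> dict:
    """Run the full bundled-dataset analysis and return the report bundle.

    The bundle holds the four-model metrics grid (integer percents), the
    two-model concordance report (with domain breakdown when annotations are
    available) and a reproducibility manifest.  With ``out_dir`` set, the
    bundle is also written as ``report.json``.
    """
    config = config or PipelineConfig()
    records = load_dataset(config.dataset_path, domains_path=None)
    domains = load_domains(config.domains_path)
    report = compare_models(
        records,
        config.resolve_model(config.model_a),
        config.resolve_model(config.model_b),
        domains=domains,
    )
    bundle = {
        "table3": table3_grid(records),
        "concordance": report.to_dict(),
        "manifest": {
            "package": "protreact",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_chemicals": len(records),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    return bundle
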