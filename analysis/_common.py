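"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from tilrep.pipeline import PipelineConfig, run_pipeline

REPO = Path(__file__).resolve().parent.parent
CONFIG = REPO / "configs" / "study.yaml"


def load_config() -> PipelineConfig:
    cfg = PipelineConfig.from_yaml(CONFIG)
    cfg.output_dir = str(REPO / cfg.output_dir)
    return cfg


def run_stage(stage: str) -> PipelineConfig:
    cfg = load_config()
    run_pipeline(cfg, stages=(stage,))
    return cfg
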