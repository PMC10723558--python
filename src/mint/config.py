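"""Schema-validated pipeline configuration (unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # paths
    items: str
    corpus: str
    out: str
    menus: Optional[str] = None
    regions: Optional[str] = None

    # behaviour
    variant: Literal["rrr", "rrr_macro"] = "rrr_macro"
    missing: Literal["error", "zero"] = "error"
    seed: int = 0

    # embeddings
    embed_dim: int = Field(300, gt=0)
    embed_epochs: int = Field(5, gt=0)

    # clustering
    reducer_params: dict = Field(default_factory=dict)
    clusterer_params: dict = Field(default_factory=dict)

    # networks
    hidden_size: int = 256
    dropout: float = Field(0.2, ge=0, lt=1)
    learning_rate: float = 1e-3
    l2: float = 1e-3
    max_epochs: int = 500
    patience: int = 10
    batch_size: int = 128
    min_finetune_items: int = 20
    finetune_weight_decay: float = 1e-3

    # prediction / aggregation
    n_mc: int = Field(100, ge=1)
    apply_outlier_filter: bool = False
    contamination: float = Field(0.03, ge=0, lt=0.5)

    def mlp_config(self):
        from .nn import MLPConfig

        return MLPConfig(
            hidden_size=self.hidden_size,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            l2=self.l2,
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
        )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; errors name the offending field."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid pipeline config (fields: {fields}): {exc}") from exc
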