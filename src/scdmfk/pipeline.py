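"""One-call pipeline: preprocess -> build -> pretrain -> joint fit."""

from __future__ import annotations

import logging
from typing import Optional

from .data_io import CountMatrix
from .model import ModelConfig, build_model
from .preprocess import prepare
from .training import FitResult, fit

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(
    matrix: CountMatrix,
    k: int,
    n_top_genes: int = 500,
    variant: str = "standard",
    sigma: float = 1.0,
    lam: float = 1.0,
    alpha: float = 1.0,
    pretrain_epochs: int = 1000,
    max_epochs: int = 300,
    tol: float = 1e-3,
    seed: int = 0,
    clip_value: Optional[float] = 10.0,
    size_factor_scope: str = "all",
    learning_rate: float = 1e-4,
    batch_size: int = 256,
) -> FitResult:
    """Cluster a raw count matrix into ``k`` groups; returns a FitResult."""
    data = prepare(
        matrix,
        n_top_genes=n_top_genes,
        clip_value=clip_value,
        size_factor_scope=size_factor_scope,
    )
    zero_frac = float((data.raw_selected == 0).mean())
    if variant == "direct" and zero_frac >= 0.7:
        logger.info(
            "zero fraction %.2f is high; the two-head 'standard' variant is "
            "usually preferable on very sparse data",
            zero_frac,
        )
    elif variant == "standard" and zero_frac < 0.7:
        logger.info(
            "zero fraction %.2f is moderate; the 'direct' softmax variant "
            "may be worth trying",
            zero_frac,
        )
    config = ModelConfig(
        variant=variant,
        alpha=alpha,
        seed=seed,
        pretrain_epochs=pretrain_epochs,
        learning_rate=learning_rate,
        batch_size=batch_size,
    )
    model = build_model(config, data.n_genes)
    return fit(
        model,
        data,
        K=k,
        sigma=sigma,
        lam=lam,
        tol=tol,
        max_epochs=max_epochs,
        pretrain_epochs=pretrain_epochs,
    )
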