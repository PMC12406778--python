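"""Token-based API cost model.

Cost is linear in token counts: a prompt token costs ``input_per_million /
1e6`` dollars, a completion token ``output_per_million / 1e6``, and one-time
costs (an embedding pass over the corpus, a fine-tune training run) are
carried as *upfront* amounts.  A campaign projection multiplies the per-call
cost by the number of calls a strategy needs — once per unique response for
the direct strategies, once per cluster for cluster labeling — and adds the
upfront amount.

Rounding discipline: totals are always computed from the *unrounded* per-call
cost; rounding (per-call to 4 decimals, upfront and totals to 2) is applied
only at display time.  9865 calls at an unrounded 0.001005 $/call is 9.91,
not the 9.87 the display-rounded 0.0010 would give.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .backends import CompletionResult
from .core import ConfigurationError, ValidationError


@dataclass(frozen=True)
class PricingModel:
    """US$ prices per million tokens, by token class."""

    input_per_million: float = 2.5
    output_per_million: float = 10.0
    embedding_per_million: float = 0.020
    training_per_million: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "input_per_million",
            "output_per_million",
            "embedding_per_million",
            "training_per_million",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "PricingModel":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class CostLine:
    """One method's cost projection; ``total`` = upfront + per_call * n_calls
    at full precision.  Use :meth:`display` for the rounded presentation."""

    method: str
    n_calls: int
    avg_prompt_tokens: float
    avg_completion_tokens: float
    upfront: float
    per_call: float
    total: float

    def display(self) -> dict:
        return {
            "method": self.method,
            "n_calls": self.n_calls,
            "avg_prompt_tokens": self.avg_prompt_tokens,
            "avg_completion_tokens": self.avg_completion_tokens,
            "upfront_usd": round(self.upfront, 2),
            "per_call_usd": round(self.per_call, 4),
            "total_usd": round(self.total, 2),
        }


def per_call_cost(
    prompt_tokens: float, completion_tokens: float, pricing: PricingModel
) -> float:
    """Unrounded US$ cost of one completion call."""
    if prompt_tokens < 0 or completion_tokens < 0:
        raise ConfigurationError("token counts must be >= 0")
    return (
        prompt_tokens * pricing.input_per_million / 1e6
        + completion_tokens * pricing.output_per_million / 1e6
    )


def embedding_cost(total_tokens: float, pricing: PricingModel) -> float:
    """Unrounded US$ cost of embedding ``total_tokens`` tokens."""
    if total_tokens < 0:
        raise ConfigurationError("token count must be >= 0")
    return total_tokens * pricing.embedding_per_million / 1e6


def training_cost(total_tokens: float, pricing: PricingModel) -> float:
    """Unrounded US$ cost of a fine-tune run over ``total_tokens`` training
    tokens."""
    if total_tokens < 0:
        raise ConfigurationError("token count must be >= 0")
    return total_tokens * pricing.training_per_million / 1e6


def campaign_cost(
    method: str,
    n_calls: int,
    avg_prompt_tokens: float,
    avg_completion_tokens: float,
    upfront: float,
    pricing: PricingModel,
) -> CostLine:
    """Project a full-campaign cost line from average token counts."""
    if n_calls < 0:
        raise ConfigurationError("n_calls must be >= 0")
    call = per_call_cost(avg_prompt_tokens, avg_completion_tokens, pricing)
    return CostLine(
        method=method,
        n_calls=n_calls,
        avg_prompt_tokens=avg_prompt_tokens,
        avg_completion_tokens=avg_completion_tokens,
        upfront=upfront,
        per_call=call,
        total=upfront + call * n_calls,
    )


def cost_table(
    lines_config: Sequence[Mapping], pricing: PricingModel
) -> list[CostLine]:
    """Build one CostLine per method spec, preserving configured order.

    Each spec is a mapping with keys method, n_calls, avg_prompt_tokens,
    avg_completion_tokens and optional upfront (default 0).
    """
    return [
        campaign_cost(
            method=spec["method"],
            n_calls=int(spec["n_calls"]),
            avg_prompt_tokens=float(spec["avg_prompt_tokens"]),
            avg_completion_tokens=float(spec["avg_completion_tokens"]),
            upfront=float(spec.get("upfront", 0.0)),
            pricing=pricing,
        )
        for spec in lines_config
    ]


def cost_table_frame(lines: Sequence[CostLine]) -> pd.DataFrame:
    """Render cost lines as a display-rounded table."""
    return pd.DataFrame([line.display() for line in lines])


def measured_cost(run_log: Iterable[CompletionResult], pricing: PricingModel) -> float:
    """Exact US$ cost of an actual run: sum of per-call costs over the log."""
    return sum(
        per_call_cost(r.prompt_tokens, r.completion_tokens, pricing)
        for r in run_log
    )


def load_campaign_config(path: str | Path | None = None) -> dict:
    """Load a campaign cost configuration: pricing plus per-method specs.

    The default ships the measured averages of the DRC vaccination-survey
    categorization campaign (9865 unique free-text strings; 200 clusters for
    the cluster-labeling strategy) at September-2024 API prices.
    """
    if path is None:
        raw = files("survcat.data").joinpath("campaign_costs.json").read_text(
            encoding="utf-8"
        )
    else:
        raw = Path(path).read_text(encoding="utf-8")
    payload = json.loads(raw)
    payload["pricing"] = PricingModel(**payload.get("pricing", {}))
    return payload
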