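"""Pre-capture pool planning.

Libraries entering a capture array differ in endogenous (on-target)
content and concentration; pooled naively, a high-content library
monopolises the baits.  The plan below makes the expected number of
on-target molecules each library contributes equal: volume fractions
proportional to ``1 / (target_content * molarity)``, so
``content * molarity * volume`` is constant across libraries — the
simplest rule achieving equal post-capture representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PoolPlan:
    """Volume fractions (summing to 1) and expected on-target share per library."""

    sample_ids: list[str]
    fractions: list[float]
    expected_on_target: list[float]

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if any(not 0.0 < f < 1.0 for f in self.fractions) and len(self.fractions) > 1:
            raise ValueError("volume fractions must be in (0, 1)")


def plan_pool(
    libraries: list[tuple[float, float]],
    sample_ids: list[str] | None = None,
    max_fraction: float | None = None,
) -> PoolPlan:
    """Equal-on-target pooling plan for ``(target_content, molarity)`` libraries.

    Fractions are invariant to rescaling all molarities (or all contents)
    by a constant.  ``max_fraction`` optionally caps any single library's
    share (0.5 is a sensible cap to stop one very poor library dominating
    the pool); capped libraries are logged, the remainder renormalised —
    equal representation then holds only among uncapped libraries.
    Libraries with non-positive content or molarity are unpoolable.
    """
    if not libraries:
        raise ValueError("no libraries to pool")
    for i, (c, m) in enumerate(libraries):
        if c <= 0 or m <= 0:
            sid = sample_ids[i] if sample_ids else f"library {i}"
            raise ValueError(f"{sid} is unpoolable: target_content and molarity must be > 0")
    if sample_ids is None:
        sample_ids = [f"lib{i}" for i in range(len(libraries))]
    weights = [1.0 / (c * m) for c, m in libraries]
    total = sum(weights)
    fractions = [w / total for w in weights]
    if max_fraction is not None and len(libraries) > 1:
        capped: set[int] = set()
        while True:
            over = [i for i in range(len(fractions)) if i not in capped and fractions[i] > max_fraction]
            if not over:
                break
            for i in over:
                log.warning("library %s capped at volume fraction %.3f", sample_ids[i], max_fraction)
                capped.add(i)
            free = [i for i in range(len(fractions)) if i not in capped]
            if not free:
                raise ValueError("cap too small: all libraries capped")
            remaining = 1.0 - max_fraction * len(capped)
            wsum = sum(weights[i] for i in free)
            for i in range(len(fractions)):
                fractions[i] = max_fraction if i in capped else weights[i] * remaining / wsum
    expected = [c * m * f for (c, m), f in zip(libraries, fractions)]
    return PoolPlan(sample_ids=list(sample_ids), fractions=fractions, expected_on_target=expected)


def read_pool_table(path: str | Path) -> tuple[list[tuple[float, float]], list[str]]:
    """Read a TSV with columns sample_id, target_content, molarity."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_content", "molarity"}
    if not required.issubset(df.columns):
        raise ValueError(f"pool table needs columns {sorted(required)}")
    libs = list(zip(df["target_content"].astype(float), df["molarity"].astype(float)))
    return libs, df["sample_id"].astype(str).tolist()


def write_pool_table(plan: PoolPlan, libraries: list[tuple[float, float]], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": plan.sample_ids,
            "target_content": [c for c, _ in libraries],
            "molarity": [m for _, m in libraries],
            "volume_fraction": plan.fractions,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
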