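"""Genotyper selection and read-subsampling arithmetic.

An ensemble run picks its member genotypers from properties of the data
rather than running all of them: reference genome size decides between
the two vg aligners, read length and sequencing depth decide whether
GraphTyper2 and/or PanGenie join, and long-read data short-circuits to
GraphAligner + vg. The plan is advisory metadata — this package never
executes the external genotypers; the merge step consumes whatever
output VCFs the user supplies.

Boundary conventions (the selection rules quote strict inequalities):
the 1 GB genome threshold is 1e9 bp, strict greater-than; at exactly
130 bp reads or 5x depth neither the GraphTyper2 ("greater than") nor
the PanGenie ("less than") condition fires, leaving only the
unconditional tools.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Mode",
    "Scope",
    "RunContext",
    "GenotypingPlan",
    "select_genotypers",
    "subsample_fraction",
    "DEFAULT_TARGET_DEPTH",
]

#: default depth (fold-coverage) reads are subsampled to before genotyping
DEFAULT_TARGET_DEPTH = 15.0

GENOME_SIZE_THRESHOLD = 1_000_000_000  # bp; "larger than 1 GB"
READ_LENGTH_THRESHOLD = 130  # bp
DEPTH_THRESHOLD = 5.0  # fold-coverage


class Mode(str, enum.Enum):
    FAST = "fast"
    PRECISE = "precise"


class Scope(str, enum.Enum):
    ALL = "all-variants"
    SV_ONLY = "sv-only"


@dataclass(frozen=True)
class RunContext:
    genome_size: int  # bp
    read_length: int  # bp
    depth: float  # fold-coverage
    long_reads: bool = False
    mode: Mode = Mode.FAST

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True)
class GenotypingPlan:
    tools: tuple[tuple[str, Scope], ...]
    subsample_fraction: float

    def __post_init__(self) -> None:
        if not self.tools:
            raise ValueError("plan must name at least one genotyper")
        if not 0.0 <= self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in [0, 1]")

    @property
    def tool_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.tools)

    def to_dict(self) -> dict:
        return {
            "tools": [{"name": name, "scope": scope.value} for name, scope in self.tools],
            "subsample_fraction": self.subsample_fraction,
        }


def select_genotypers(ctx: RunContext) -> GenotypingPlan:
    """Deterministic genotyper choice from the run context.

    Short reads: BayesTyper always; Paragraph (SV-only in fast mode,
    all variants in precise mode); vg giraffe for genomes > 1 Gb else
    vg map; GraphTyper2 when reads > 130 bp AND depth > 5x; PanGenie
    additionally when depth < 5x OR reads < 130 bp. Long reads: the
    GraphAligner + vg plan, ignoring the short-read rules.
    """
    frac = (
        min(1.0, DEFAULT_TARGET_DEPTH / ctx.depth) if ctx.depth > 0 else 1.0
    )
    if ctx.long_reads:
        return GenotypingPlan(
            tools=(("GraphAligner", Scope.ALL), ("vg", Scope.ALL)),
            subsample_fraction=frac,
        )
    tools: list[tuple[str, Scope]] = [
        ("BayesTyper", Scope.ALL),
        ("Paragraph", Scope.SV_ONLY if ctx.mode is Mode.FAST else Scope.ALL),
    ]
    if ctx.genome_size > GENOME_SIZE_THRESHOLD:
        tools.append(("vg giraffe", Scope.ALL))
    else:
        tools.append(("vg map", Scope.ALL))
    if ctx.read_length > READ_LENGTH_THRESHOLD and ctx.depth > DEPTH_THRESHOLD:
        tools.append(("GraphTyper2", Scope.ALL))
    if ctx.depth < DEPTH_THRESHOLD or ctx.read_length < READ_LENGTH_THRESHOLD:
        tools.append(("PanGenie", Scope.ALL))
    return GenotypingPlan(tools=tuple(tools), subsample_fraction=frac)


def subsample_fraction(
    total_bases: float, genome_size: float, target_depth: float = DEFAULT_TARGET_DEPTH
) -> float:
    """Fraction of reads to keep so coverage lands at target_depth.

    min(1, target_depth * genome_size / total_bases); never up-samples.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return min(1.0, target_depth * genome_size / total_bases)
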