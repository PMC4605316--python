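"""Pipeline configuration.

All thresholds of the discovery cascade live here so that a run is fully
described by one object: abundance/recurrence cut-offs, alignment and duplex
mismatch budgets, the hairpin/motif geometry used for Microprocessor
(Drosha/DGCR8) signatures, and the statistical screens.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration value is inconsistent or out of range."""


@dataclass
class PipelineConfig:
    """Thresholds and options for the rsRNA discovery cascade.

    Defaults encode the published cascade: reads kept when a condition
    accumulates at least ``min_reads`` copies and the sequence recurs in at
    least ``min_conditions`` distinct experimental conditions; genome and
    duplex matching allow at most two substitutions; hairpin analysis uses
    100 bp flanks; differential expression requires a two-fold change; the
    anti-correlation screen requires Pearson r <= -0.5 at p <= 0.05.
    """

    min_reads: int = 5
    min_conditions: int = 2
    max_genome_mismatches: int = 2
    max_duplex_mismatches: int = 2
    flank_bp: int = 100
    fold_change_min: float = 2.0
    pcc_max: float = -0.5
    p_max: float = 0.05
    pseudocount: float = 0.5
    # Drosha processing motif geometry (offsets relative to the precursor).
    cnnc_center: int = 17
    cnnc_tolerance: int = 2
    basal_u_pos: int = -14
    basal_g_pos: int = -13
    stem_tolerance_nt: int = 2
    min_stem_pairs: int = 16
    min_loop_nt: int = 3
    clash_slop_nt: int = 25
    rng_seed: int = 0
    # Secondary knobs (each documented at its point of use).
    max_bulge_nt: int = 2              # total bulged nt allowed along a hairpin stem
    known_mirna_max_mm: int = 0        # substitutions allowed when excluding known miRNAs
    clash_srna_max_mm: int = 1         # substitutions allowed matching chimera sRNA segments
    wobble_allowance: int = 0          # number of G:U pairs not counted as duplex mismatches
    clip_require_read: bool = True     # AGO support = peak overlap AND sRNA in the read set
    kd_absent_max: int = 0             # "totally absent in knockdown" = count <= this
    log_transform_correlations: bool = False
    scan_regions: tuple[str, ...] = ("3UTR",)

    def validate(self) -> "PipelineConfig":
        positive = [
            "min_reads", "min_conditions", "flank_bp", "fold_change_min",
            "pseudocount", "cnnc_center", "min_stem_pairs", "min_loop_nt",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        non_negative = [
            "max_genome_mismatches", "max_duplex_mismatches", "cnnc_tolerance",
            "stem_tolerance_nt", "clash_slop_nt", "max_bulge_nt",
            "known_mirna_max_mm", "clash_srna_max_mm", "wobble_allowance",
            "kd_absent_max",
        ]
        for name in non_negative:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.pcc_max >= 0:
            raise ConfigError("pcc_max must be negative (anti-correlation threshold)")
        if not (0 < self.p_max <= 1):
            raise ConfigError("p_max must lie in (0, 1]")
        bad = set(self.scan_regions) - {"3UTR", "5UTR", "CDS"}
        if bad:
            raise ConfigError(f"unknown scan regions: {sorted(bad)}")
        return self

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a ``key = value`` text config; unknown keys are rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(fields[key].type, value)
        return cls(**kwargs).validate()

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(type_name: str, value: str):
    if type_name == "int":
        return int(value)
    if type_name == "float":
        return float(value)
    if type_name == "bool":
        if value.lower() in {"true", "1", "yes"}:
            return True
        if value.lower() in {"false", "0", "no"}:
            return False
        raise ConfigError(f"cannot parse boolean from {value!r}")
    if type_name.startswith("tuple"):
        return tuple(part.strip() for part in value.split(",") if part.strip())
    return value
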