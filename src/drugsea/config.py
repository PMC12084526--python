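"""YAML-driven run configuration for the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .io import ValidationError


@dataclass
class DisorderInputs:
    """Per-disorder input paths; eQTL and loop tables are optional."""

    sumstats: str
    eqtl: Optional[str] = None
    loops: Optional[str] = None


@dataclass
class RunConfig:
    genes: str
    targets: str
    indications: str
    disorders: dict[str, DisorderInputs]
    outdir: str = "drugsea_out"
    gws_alpha: float = 5e-8
    flank: int = 10_000
    clump_window: int = 250_000
    promoter_flank: int = 2_000
    sources: list[str] = field(default_factory=lambda: ["proximity"])
    modes: list[str] = field(default_factory=lambda: ["binary"])
    n_perm: int = 0            # 0 disables permutation testing
    seed: int = 0
    alpha: float = 0.05
    cluster_on_class: bool = False
    column_map: Optional[dict[str, str]] = None

    def __post_init__(self):
        # accept plain dicts / bare paths for disorder inputs
        self.disorders = {
            name: spec if isinstance(spec, DisorderInputs)
            else DisorderInputs(**spec) if isinstance(spec, dict)
            else DisorderInputs(sumstats=spec)
            for name, spec in (self.disorders or {}).items()
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"bad config key: {exc}") from exc

    def validate_paths(self) -> None:
        """Every referenced input must exist before the run starts."""
        missing = [p for p in self._all_paths() if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")

    def _all_paths(self):
        paths = [self.genes, self.targets, self.indications]
        for d in self.disorders.values():
            paths.append(d.sumstats)
            paths.extend(p for p in (d.eqtl, d.loops) if p)
        return paths

    def hash(self) -> str:
        """Short stable digest of the scientific configuration (the output
        directory does not affect results and is excluded), stamped on outputs."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        return f"drugsea config={self.hash()} seed={self.seed}"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
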