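"""Pipeline configuration: one audited source for every threshold.

Defaults are the screen's canonical values: MAF >= 0.05, association
p < 1e-5, +/- 1 kb gene window, gene sets kept at >= 5 genes, ES > 0.25 and
p < 0.05, integrated rate-covariation score > 2 over >= 8 shared branches.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from modscreen.simulate import SimConfig


@dataclass
class PipelineConfig:
    # stage toggles
    run_screen: bool = True
    run_gwa: bool = True
    run_annotate: bool = True
    run_gsea: bool = True
    run_erc: bool = True
    run_enrich: bool = True

    # thresholds (screen-canonical defaults)
    min_maf: float = 0.05
    max_missing: float = 0.2
    assoc_p_threshold: float = 1e-5
    gene_window: int = 1000
    gsea_min_size: int = 5
    gsea_min_es: float = 0.25
    gsea_max_p: float = 0.05
    gsea_n_perm: int = 1000
    erc_hit_threshold: float = 2.0
    erc_min_branches: int = 8
    lmm_mode: str = "emmax"
    lmm_method: str = "reml"
    wald_reference: str = "chisq"
    cross_n_expected: int = 100
    focal_gene: str = "gene_0000"

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        cfg = cls(**raw, sim=SimConfig(**sim_raw))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sim"]["maf_range"] = list(data["sim"]["maf_range"])
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
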