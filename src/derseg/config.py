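"""Run configuration shared by the model layer, the permutation null, and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the documented defaults.

    Attributes
    ----------
    offset : float
        Pseudo-count added before the log2 transform.
    cutoff_c : float
        Average-coverage threshold separating expressed from unexpressed
        bases; also sets the prior for the no-expression state.
    delta : float
        Emission variance of the no-expression state (tiny, pins the
        statistic at 0).
    retain_prob : float
        Diagonal of the fixed transition matrix; 0.999 gives expected
        segment lengths of roughly a kilobase, matching gene-scale
        sparsity.
    library_norm : str
        "log2" includes log2(library size) as a confounder, "none" omits it.
    library_method : str
        Depth summary: "median" or "q75".
    B : int
        Number of label permutations for the null pool.
    pvalue_mode / sided : str
        "pseudocount" (default, strictly positive p) or "exact";
        "two" or "one" sided comparison against the null pool.
    stat_mode : str
        Region statistic: "sum" of base statistics over the region
        (default; rewards sustained signal and suppresses one-base noise
        spikes) or "mean".
    """

    offset: float = 0.5
    cutoff_c: float = 5.0
    delta: float = 1e-4
    retain_prob: float = 0.999
    library_norm: str = "log2"
    library_method: str = "median"
    mixture_max_iter: int = 500
    mixture_tol: float = 1e-8
    B: int = 50
    seed: int = 1
    pvalue_mode: str = "pseudocount"
    sided: str = "two"
    fdr_threshold: float = 0.05
    stat_mode: str = "sum"
    segment_on: str = "magnitude"   # fold the t-track for segmentation; "signed" keeps raw
    q_threshold: float = 0.05
    exon_frac_threshold: float = 0.2
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        extra = data.pop("extra", {})
        data.update(extra)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
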