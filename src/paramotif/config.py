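"""Run configuration: every pipeline tunable with its default."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional

from .scan import ScanParams


@dataclass
class RunConfig:
    """All tunables of the detection pipeline.

    Defaults follow the method's published operating point: k = 11 motif
    length, base quality >= 10 at motif positions, spacing tolerance D = 10,
    50% palindrome and 30% unexplained-sequence filters, clustering
    alpha = 10 / beta = 0.5, and four total copies (two gene + two pseudogene
    per diploid genome).  ``max_skip`` is unbounded by default: the
    distance-scaled spacing check, not the id gap, separates real junctions
    from error-induced motif losses (see docs/methods.md).
    """

    k: int = 11
    min_qual: int = 10
    max_dist: int = 10
    drift_frac: float = 0.05
    max_skip: Optional[int] = None
    max_palindrome_frac: float = 0.5
    max_unexplained_frac: float = 0.30
    alpha: float = 10.0
    beta: float = 0.5
    beta_basis: str = "reads"
    min_reads: int = 3
    total_copies: int = 4
    pcr_chimera_frac: float = 0.05
    vaf_tol: float = 0.08
    n_haplotypes: int = 2
    phase_window: int = 25
    min_identity: float = 0.80
    seed: int = 0

    def scan_params(self) -> ScanParams:
        return ScanParams(
            min_qual=self.min_qual,
            max_dist=self.max_dist,
            drift_frac=self.drift_frac,
            max_skip=self.max_skip,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]
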