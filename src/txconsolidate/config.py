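"""Run configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    """All thresholds of the two-tiered consolidation workflow.

    Defaults are the workflow's standard operating point: 90% mapping
    coverage, GT-AG splice sites, 75% locus-ORF fraction, 90%/95%-identity
    ungapped containment, 95% cross-branch merge coverage, 90%-coverage /
    1%-gap / 90%-identity classification, 80%-coverage u80 metric and a
    5-point identity-drop presence test.
    """

    seed: int = 0
    min_orf_nt: int = 200
    mapping_cov: float = 0.90
    canonical_pairs: str = "GT-AG"
    orf_fraction: float = 0.75
    dedupe_cov: float = 0.90
    dedupe_identity: float = 95.0
    cluster_k: int = 14
    cluster_shared_fraction: float = 0.30
    assemble_min_overlap: int = 40
    assemble_identity: float = 98.0
    merge_cov: float = 0.95
    merge_identity: float = 90.0
    classify_ref_cov: float = 0.90
    classify_query_cov: float = 0.90
    classify_max_gap: float = 0.01
    classify_identity: float = 90.0
    u80_cov: float = 0.80
    u80_identity: float = 70.0
    identity_drop: float = 5.0

    def __post_init__(self):
        for name in ("mapping_cov", "orf_fraction", "dedupe_cov", "merge_cov",
                     "classify_ref_cov", "classify_query_cov", "u80_cov"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def canonical_pair_set(self) -> frozenset[tuple[str, str]]:
        pairs = set()
        for token in self.canonical_pairs.split(","):
            token = token.strip()
            if not token:
                continue
            donor, _, acceptor = token.partition("-")
            pairs.add((donor.upper(), acceptor.upper()))
        return frozenset(pairs)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.md5(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load ``key = value`` lines; keyword overrides win over the file."""
        values: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, eq, value = line.partition("=")
                key = key.strip()
                if not eq or key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown config line {raw!r}")
                values[key] = value.strip()
        cfg = cls()
        typed: dict = {}
        for key, value in values.items():
            current = getattr(cfg, key)
            typed[key] = type(current)(value)
        typed.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**typed)
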