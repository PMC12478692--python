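"""Run configuration: every tunable of the pipeline in one validated record.

Defaults encode the main-results configuration: spectral cut fractions
(p, q) = (0.01, 0.03), one-hot fusion enabled, Cα contact graphs at a
10 Å threshold with the normalized Laplacian.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # contact graph
    contact_threshold: float = 10.0  # Å, strict <
    atom: str = "CA"
    laplacian_kind: str = "normalized"
    # spectral bands
    p: float = 0.01
    q: float = 0.03
    # pooling / model widths
    s: int = 8  # super-nodes per scale
    c: int = 32  # attention width
    d: int = 128  # node feature width
    max_len: int = 1024  # descriptor padding length
    context_width: int = 32  # contextual embedding width (mock provider)
    use_onehot: bool = True
    descriptor_which: str = "smallest"
    # optimizer
    epochs: int = 50
    batch_size: int = 16
    lr: float = 1e-3
    # randomness
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not (0.0 < self.p < self.q < 1.0):
            raise ValueError(
                f"config requires 0 < p < q < 1, got p={self.p}, q={self.q}"
            )
        if self.s < 1:
            raise ValueError("s (super-node count) must be >= 1")
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if self.laplacian_kind not in ("combinatorial", "normalized"):
            raise ValueError("laplacian_kind must be combinatorial or normalized")
        if self.descriptor_which not in ("smallest", "largest"):
            raise ValueError("descriptor_which must be smallest or largest")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        """Write the resolved configuration (every run snapshots this)."""
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def configure_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    logger = logging.getLogger("bandfold")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
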