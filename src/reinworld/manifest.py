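"""Run manifests and logging: every artefact a run writes, listed with the
fully resolved configuration and seed that reproduce it."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

from . import __version__

log = logging.getLogger("reinworld")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


@dataclass
class RunManifest:
    """Provenance record of one run."""

    command: str
    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.UTC).isoformat()
        log.info("run start: %s seed=%s", self.command, self.seed)
        return self

    def add_output(self, path) -> None:
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        self.outputs.append({"path": str(path), "sha256": digest})
        log.info("wrote %s (sha256 %s)", path, digest[:12])

    def write(self, path) -> None:
        self.finished = datetime.datetime.now(datetime.UTC).isoformat()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        log.info("manifest written: %s", path)


def ensure_outdir(prefix: str) -> None:
    """Fail fast, before any compute, if the output directory is missing
    or unwritable."""
    d = os.path.dirname(os.path.abspath(str(prefix) + "_probe"))
    if not os.path.isdir(d):
        raise FileNotFoundError(f"output directory does not exist: {d}")
    if not os.access(d, os.W_OK):
        raise PermissionError(f"output directory not writable: {d}")
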