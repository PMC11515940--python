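"""End-to-end run driver: simulate -> map -> pileup -> profile -> call.

A run is described by a :class:`RunConfig`; everything downstream of the
seed is deterministic, and the manifest written next to the outputs records
inputs, parameters, package version and seed so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .caller import call_sites, profile
from .io import (
    read_template_meta,
    write_calls,
    write_fastq,
    write_manifest,
    write_pileup_tsv,
    write_profile_tsv,
    write_truth,
)
from .simulate import ARMS, SimParams, simulate_library
from .stopmap import ReferenceSet, map_reads, pileup
from .templates import RnaTemplate


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    meta_path: str
    out_dir: str
    fasta_path: str | None = None
    params: SimParams = field(default_factory=SimParams)
    seed: int = 0
    arms: tuple[str, ...] = ("input", "cmc_only", "cmc_xrn1")
    tau_t: float = 0.3
    tau_delta: float = 0.1
    min_cov: int = 50
    verbosity: int = 1

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["arms"] = list(self.arms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["params"] = SimParams.from_dict(d["params"])
        d["arms"] = tuple(d["arms"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every arm of a run and write all artifacts; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    templates = read_template_meta(config.meta_path, config.fasta_path)
    refs = ReferenceSet(templates)
    params = SimParams.from_dict({**config.params.to_dict(), "seed": config.seed})

    profiles: dict[tuple[str, str], object] = {}  # (arm, ref_id) -> TerminationProfile
    outputs: list[Path] = []
    # each arm gets an independent, reproducible stream
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.arms))
    for arm, ss in zip(config.arms, seeds):
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}")
        rng = np.random.default_rng(ss)
        reads, truth = simulate_library(templates, params, arm, rng)
        fq = out / f"{arm}.fastq"
        write_fastq(reads, fq)
        tt = out / f"{arm}.truth.tsv"
        write_truth(truth, tt, params, arm)
        outputs += [fq, tt]

        alns = map_reads(reads, refs)
        for tpl in templates:
            pu = pileup(alns, tpl)
            pu_path = out / f"{arm}.{tpl.id}.pileup.tsv"
            write_pileup_tsv(pu, tpl.sequence, pu_path, {"arm": arm, "seed": config.seed})
            prof = profile(pu, min_cov=config.min_cov, arm=arm)
            prof_path = out / f"{arm}.{tpl.id}.profile.tsv"
            write_profile_tsv(prof, prof_path, {"arm": arm, "seed": config.seed})
            profiles[(arm, tpl.id)] = prof
            outputs += [pu_path, prof_path]

    calls_written = []
    if "cmc_xrn1" in config.arms and "cmc_only" in config.arms:
        for tpl in templates:
            treated = profiles[("cmc_xrn1", tpl.id)]
            control = profiles[("cmc_only", tpl.id)]
            input_prof = profiles.get(("input", tpl.id))
            calls = call_sites(
                treated, control, input_prof,
                tau_t=config.tau_t, tau_delta=config.tau_delta, min_cov=config.min_cov,
            )
            path = out / f"calls.{tpl.id}.tsv"
            write_calls(calls, path, {"seed": config.seed, "ref": tpl.id})
            outputs.append(path)
            calls_written.append((tpl.id, len(calls)))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "arms": list(config.arms),
        "params": params.to_dict(),
        "inputs": {"meta": str(config.meta_path), "fasta": str(config.fasta_path or "")},
        "thresholds": {
            "tau_t": config.tau_t, "tau_delta": config.tau_delta, "min_cov": config.min_cov,
        },
        "templates": [t.id for t in templates],
        "calls": {ref: n for ref, n in calls_written},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest
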