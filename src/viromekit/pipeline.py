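"""Stage orchestration: run a configured sequence of analysis stages with
derived per-stage seeds and a reproducibility manifest.

A run config (YAML or dict) names an output directory, a global seed and
an ordered list of stages.  Each stochastic stage gets a seed derived
deterministically from the global seed and the stage's position, so any
stage can be re-run in isolation.  The manifest records parameters, seeds
and SHA-256 checksums of every input and output file; re-running an
identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml

from . import clusterdiv, seqio, specrich, synthdata

STAGES = ("simulate", "dedup", "subsample", "cluster", "rarefy", "spectrum",
          "fit_richness")


def derive_seed(global_seed: int, stage_index: int) -> int:
    """Per-stage seed: stable hash of (global seed, stage position)."""
    h = hashlib.sha256(f"{global_seed}:{stage_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> None:
    for key in ("out_dir", "seed", "stages"):
        if key not in config:
            raise ValueError(f"config missing required field {key!r}")
    for i, st in enumerate(config["stages"]):
        if "stage" not in st:
            raise ValueError(f"stage {i} missing 'stage' field")
        if st["stage"] not in STAGES:
            raise ValueError(
                f"unknown stage {st['stage']!r}; supported: {STAGES}"
            )
        if st["stage"] in ("dedup", "subsample", "cluster", "rarefy",
                           "spectrum") and "input" not in st:
            raise ValueError(f"stage {i} ({st['stage']}) missing 'input' path")


def run(config: dict) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    A stage failure halts the run with the failing stage named; outputs
    of completed stages are retained.
    """
    validate_config(config)
    out_dir = config["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": config["seed"], "stages": [], "outputs": {}}
    current: seqio.ReadSet | None = None
    spectrum: specrich.ContigSpectrum | None = None

    for i, st in enumerate(config["stages"]):
        stage = st["stage"]
        seed = derive_seed(config["seed"], i)
        entry = {"stage": stage, "seed": seed,
                 "params": {k: v for k, v in st.items() if k != "stage"}}
        try:
            if stage == "simulate":
                comm = synthdata.make_community(
                    S=st["S"], genome_len=st.get("genome_len", 10000),
                    family=st.get("family", "power"),
                    params=st.get("params"), seed=seed)
                p = synthdata.ReadSimParams(
                    n_reads=st["n_reads"], read_len=st["read_len"],
                    error_rate=st.get("error_rate", 0.0),
                    dup_fraction=st.get("dup_fraction", 0.0), seed=seed)
                current = synthdata.simulate_reads(comm, p, name=st.get(
                    "name", "sim"))
                path = os.path.join(out_dir, f"{current.name}.fasta")
                seqio.write_fasta(current, path)
                entry["output"] = path
            elif stage == "dedup":
                rs = _resolve(st, current)
                current, removed = seqio.dedup_exact(rs)
                entry["n_removed"] = removed
                path = os.path.join(out_dir, f"{current.name}.dedup.fasta")
                seqio.write_fasta(current, path)
                entry["output"] = path
            elif stage == "subsample":
                rs = _resolve(st, current)
                current = seqio.subsample(rs, n=st["n"],
                                          trim_len=st.get("trim_len"),
                                          seed=seed)
                path = os.path.join(out_dir, f"{current.name}.sub.fasta")
                seqio.write_fasta(current, path)
                entry["output"] = path
            elif stage == "cluster":
                rs = _resolve(st, current)
                sol = clusterdiv.greedy_cluster(rs, st.get("threshold", 0.75))
                path = os.path.join(out_dir, f"{rs.name}.clusters.tsv")
                clusterdiv.write_cluster_tsv(sol, path)
                entry["n_clusters"] = sol.n_clusters
                entry["output"] = path
            elif stage == "rarefy":
                rs = _resolve(st, current)
                curve = clusterdiv.rarefy(rs, st.get("threshold", 0.75),
                                          step=st.get("step", 1000), seed=seed)
                path = os.path.join(out_dir, f"{rs.name}.rarefaction.tsv")
                clusterdiv.write_curve_tsv(curve, path)
                entry["output"] = path
            elif stage == "spectrum":
                rs = _resolve(st, current)
                _, spectrum = specrich.assemble_strict(
                    rs, min_identity=st.get("min_identity", 0.98),
                    min_overlap=st.get("min_overlap", 35))
                path = os.path.join(out_dir, f"{rs.name}.spectrum.tsv")
                specrich.write_spectrum_tsv(spectrum, path)
                entry["output"] = path
            elif stage == "fit_richness":
                if spectrum is None:
                    raise ValueError("fit_richness requires a prior spectrum "
                                     "stage")
                lw = specrich.LWParams(
                    read_len=st["read_len"],
                    min_overlap=st.get("min_overlap", 35),
                    avg_genome_len=st["avg_genome_len"])
                est = specrich.fit_richness(spectrum, lw)
                result = {"S_hat": est.S_hat,
                          "family": est.best_model.family,
                          "params": est.best_model.params,
                          "shannon": est.shannon, "evenness": est.evenness}
                path = os.path.join(out_dir, "richness.json")
                with open(path, "w") as fh:
                    json.dump(result, fh, indent=1)
                entry.update(result)
                entry["output"] = path
        except Exception as exc:
            raise RuntimeError(f"stage {i} ({stage}) failed: {exc}") from exc
        if "output" in entry:
            manifest["outputs"][entry["output"]] = _sha256(entry["output"])
        manifest["stages"].append(entry)

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _resolve(st: dict, current: seqio.ReadSet | None) -> seqio.ReadSet:
    src = st.get("input", "previous")
    if src == "previous":
        if current is None:
            raise ValueError("stage expects a previous stage's read set")
        return current
    if not os.path.exists(src):
        raise ValueError(f"input file not found: {src}")
    fmt = "fastq" if src.endswith(("fastq", "fq")) else "fasta"
    return seqio.read_sequences(src, fmt)


def report(manifest: dict) -> str:
    """Human-readable run summary (no recomputation); idempotent."""
    lines = ["# viromekit run report", ""]
    lines.append(f"global seed: {manifest.get('seed', 'n/a')}")
    lines.append("")
    lines.append("## Stages")
    stages = manifest.get("stages", [])
    if not stages:
        lines.append("(none)")
    for i, st in enumerate(stages):
        extras = {k: v for k, v in st.items()
                  if k not in ("stage", "seed", "params", "output")}
        lines.append(f"{i}. {st['stage']} (seed {st['seed']})"
                     + (f" -> {st['output']}" if "output" in st else "")
                     + (f" {extras}" if extras else ""))
    lines.append("")
    lines.append("## Output checksums")
    outputs = manifest.get("outputs", {})
    if not outputs:
        lines.append("(none)")
    for path, digest in sorted(outputs.items()):
        lines.append(f"- {path}: sha256 {digest[:16]}...")
    return "\n".join(lines) + "\n"
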