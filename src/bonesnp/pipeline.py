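"""End-to-end simulated study runner.

Glues the stages together the way a bone-identification study is analysed:
simulate a cohort (reference replicates at nanogram input, challenging
libraries at picogram input with possible contamination) → threshold calling
→ reference profiles from replicates → Turchi consensus from the challenging
libraries → per-sample ADO/ADI accounting against the reference → the
≥19-marker filter → three-setting semi-continuous LRs (and optionally the
continuous model) → cohort report. Every artifact is written under the
output directory together with a manifest carrying the seed and a hash of
the configuration, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io
from .calling import CallThresholds, call_profile
from .core import LRParams, make_panel
from .diagnostics import cohort_report, render_report, y_haplotype_compare
from .profiles import (
    build_consensus,
    build_reference,
    concordance_stats,
    min_marker_filter,
)
from .semicontinuous import estimate_dropout, profile_lr
from .simulate import SimulationConfig, sample_frequencies, simulate_cohort


@dataclass
class RunConfig:
    """Configuration of a simulated end-to-end run."""

    out_dir: str
    seed: int = 1
    n_autosomal: int = 90
    n_y: int = 34
    n_challenging: int = 15
    n_reference_per_donor: int = 3
    n_donors: int = 3
    min_markers: int = 19
    theta: float = 0.01
    run_continuous: bool = False
    contamination_prob: float = 0.4
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = CallThresholds(**raw["thresholds"])
        if "simulation" in raw:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir")  # where artifacts land does not change the science
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _clip_rate(x: float) -> float:
    """Clamp an empirical frequency into the open parameter domain [0, 1)."""
    return min(x, 0.99)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated study; returns the cohort report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = make_panel(config.n_autosomal, config.n_y, seed=config.seed)
    freqs = sample_frequencies(panel, seed=config.seed + 1)
    io.write_panel_tsv(panel, out / "panel.tsv")
    io.write_frequency_csv(freqs, out / "frequencies.csv")

    samples, manifest = simulate_cohort(
        panel,
        freqs,
        n_challenging=config.n_challenging,
        n_reference_per_donor=config.n_reference_per_donor,
        n_donors=config.n_donors,
        seed=config.seed,
        base_cfg=config.simulation,
        contamination_prob=config.contamination_prob,
    )
    io.write_counts_tsv([s.counts for s in samples], out / "counts.tsv")

    profiles = {s.sample_id: call_profile(s.counts, panel, config.thresholds) for s in samples}
    for sid, profile in profiles.items():
        io.write_profile_json(profile, out / f"profile_{sid}.json")

    references = {}
    for donor_id in sorted({s.donor_id for s in samples}):
        reps = [profiles[s.sample_id] for s in samples if s.role == "reference" and s.donor_id == donor_id]
        if len(reps) >= 2:
            references[donor_id] = build_reference(reps)
            io.write_profile_json(references[donor_id], out / f"reference_{donor_id}.json")

    consensus = {}
    for donor_id in references:
        group = [
            profiles[s.sample_id]
            for s in samples
            if s.role == "challenging" and s.donor_id == donor_id
        ]
        if len(group) >= 2:
            consensus[donor_id] = build_consensus(group)
            io.write_profile_json(consensus[donor_id], out / f"consensus_{donor_id}.json")

    challenging = [s for s in samples if s.role == "challenging"]
    retained_ids = {
        p.sample_id
        for p in min_marker_filter(
            [profiles[s.sample_id] for s in challenging], config.min_markers
        )
    }

    rows = []
    for s in challenging:
        profile = profiles[s.sample_id]
        reference = references.get(s.donor_id)
        if reference is None:
            continue
        summary = concordance_stats(profile, reference)
        row: dict = {
            "sample_id": s.sample_id,
            "donor_id": s.donor_id,
            "n_typed": profile.typed_autosomal(),
            "template_pg": round(s.template_pg, 3),
            "contaminant_fraction": round(s.contaminant_fraction, 4),
            "ado_freq": summary.ado_freq,
            "adi_freq": summary.adi_freq,
            "maf_flag_freq": summary.maf_flag_freq,
        }
        if profile.sample_id in retained_ids and profile.typed_autosomal() > 0:
            d_e = estimate_dropout(profile, reference, c=0.05, freqs=freqs, theta=config.theta)
            for setting, params in {
                "LRd": LRParams(0.1, 0.05, config.theta, "default"),
                "LRe": LRParams(d_e, 0.05, config.theta, "estimated"),
                "LRa": LRParams(
                    _clip_rate(summary.ado_freq or 0.0),
                    _clip_rate(summary.adi_freq or 0.0),
                    config.theta,
                    "actual",
                ),
            }.items():
                result = profile_lr(profile, reference, params, freqs)
                row[f"log10_{setting}"] = result.log10_lr
            if config.run_continuous:
                from .continuous import continuous_lr

                try:
                    row["log10_LRq"] = continuous_lr(
                        s.counts, reference, freqs, theta=config.theta
                    ).log10_lr
                except (ValueError, RuntimeError):
                    pass
            try:
                ycmp = y_haplotype_compare(profile, reference)
                row["y_dropins"] = ycmp.dropins
                row["y_typed"] = ycmp.typed
            except ValueError:
                pass
        rows.append(row)

    if not rows:
        raise ValueError("pipeline produced no challenging-sample rows")

    report = cohort_report(rows, min_markers=config.min_markers)
    report["manifest"] = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "truth": manifest,
    }
    (out / "report.json").write_text(io.canonical_json(_jsonable(report)))
    (out / "report.txt").write_text(render_report(report))
    return report


def _jsonable(obj):
    """Map -inf/nan to JSON-safe sentinels recursively."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else ("-1e9999" if obj < 0 else "1e9999")
    return obj
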