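"""End-to-end pipeline: simulate -> features -> fit -> tables -> limits.

One :class:`RunConfig` drives every stage; all outputs (CSV/JSON) are written
with stable formatting, and a manifest records the resolved configuration,
seed and SHA-256 of each artifact, so re-running with the same configuration
reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calibration import StaircaseProtocol
from .cohort import asymmetry_limits, descriptive_table, icc
from .features import FeatureConfig, extract_ear_features
from .io import (SubjectRecord, sha256_file, write_feature_csv,
                 write_model_json, write_trace)
from .reference import (ClassificationCriteria, FitConfig,
                        ReferenceIntervalModel, classify_subject)
from .simulate import (CohortConfig, WaveformConfig, cohort_to_frame,
                       sample_cohort, synth_session)

__all__ = ["RunConfig", "run_pipeline", "sessions_to_records"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "cvemp_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    protocol: StaircaseProtocol = field(default_factory=StaircaseProtocol)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    criteria: ClassificationCriteria = field(default_factory=ClassificationCriteria)
    write_traces: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # location metadata; keeps manifests comparable
        return json.loads(json.dumps(d, default=str))


def sessions_to_records(subjects, config: RunConfig) -> list[SubjectRecord]:
    """Synthesize each subject's session and extract its feature rows."""
    records: list[SubjectRecord] = []
    trace_dir = Path(config.out_dir) / "traces" if config.write_traces else None
    if trace_dir is not None:
        trace_dir.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        session = synth_session(subj, config.protocol, config.waveform)
        for (ear, mode), recording in sorted(session.items()):
            feats, thr = extract_ear_features(recording, config.protocol,
                                              config.features)
            records.append(SubjectRecord(
                subject_id=subj.id, group=subj.group, age_years=subj.age_years,
                sex=subj.sex, ear=ear, mode=mode,
                pn_uv=feats.pn_uv if feats.response_present else None,
                emg_uv=feats.emg_uv,
                amplitude_ratio=feats.amplitude_ratio,
                p_latency_ms=feats.p_latency_ms,
                n_latency_ms=feats.n_latency_ms,
                threshold_dbnhl=thr.threshold_dbnhl,
                response_present=thr.threshold_dbnhl is not None,
            ))
            if trace_dir is not None:
                for level, traces in sorted(recording.items()):
                    for t in traces:
                        write_trace(t, trace_dir / (
                            f"{subj.id}_{ear}_{mode}_{level:g}dBnHL_r{t.replicate}.txt"))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = sha256_file(path)
        return path

    # 1. simulate
    subjects = sample_cohort(config.cohort, seed=config.seed,
                             protocol=config.protocol)
    truth = cohort_to_frame(subjects)
    save("cohort_truth.csv",
         lambda p: truth.to_csv(p, index=False, float_format="%.6g"))

    # 2. features
    records = sessions_to_records(subjects, config)
    save("features.csv", lambda p: write_feature_csv(records, p))
    from .io import records_to_frame
    df = records_to_frame(records)

    # 3. reference-interval fits per mode (sex strata, shared lambda)
    results = {}
    for mode in ("AC", "BC"):
        sub = df[(df["mode"] == mode) & df["response_present"]]
        model = ReferenceIntervalModel.from_dataframe(
            sub, mode=mode, config=config.fit)
        res = model.fit()
        results[mode] = res
        save(f"model_{mode}.json", lambda p, r=res: write_model_json(r, p))
        table = res.normative_table()
        save(f"normative_{mode}.csv",
             lambda p, t=table: t.to_csv(p, index=False, float_format="%.4f"))

    # 4. asymmetry limits + ICC per mode
    stats_obj = {}
    for mode in ("AC", "BC"):
        sub = df[(df["mode"] == mode) & df["amplitude_ratio"].notna()]
        wide = sub.pivot_table(index="subject_id", columns="ear",
                               values="amplitude_ratio", aggfunc="first")
        pairs = wide.dropna()[["R", "L"]].to_numpy()
        lim = asymmetry_limits(pairs, mode=mode)
        agreement = icc(pairs)
        stats_obj[mode] = {
            "asymmetry_lower_pct": round(lim.lower, 4),
            "asymmetry_upper_pct": round(lim.upper, 4),
            "coverage_pct": lim.coverage, "n_pairs": lim.n,
            "quantile_rule": lim.quantile_rule,
            "icc": round(agreement.estimate, 4),
            "icc_ci": [round(agreement.ci_lower, 4), round(agreement.ci_upper, 4)],
        }
    save("asymmetry_limits.json",
         lambda p: p.write_text(json.dumps(stats_obj, indent=1, sort_keys=True) + "\n"))

    # 5. descriptive table
    desc = descriptive_table(df)
    save("descriptive.csv", lambda p: desc.to_csv(p, float_format="%.4f"))

    # 6. classification demo: first child subject, AC
    child = df[(df["group"] == "child") & (df["mode"] == "AC")]
    first = child[child["subject_id"] == child["subject_id"].iloc[0]]
    from .io import frame_to_records
    cls = classify_subject(results["AC"], frame_to_records(first), config.criteria)
    save("classification_demo.json", lambda p: p.write_text(json.dumps(
        {"subject_id": first["subject_id"].iloc[0],
         "z": {k: round(v, 4) for k, v in cls.z.items()},
         "centile": {k: round(v, 3) for k, v in cls.centile.items()},
         "flags": cls.flags, "overall": cls.overall},
        indent=1, sort_keys=True) + "\n"))

    manifest = {
        "package": "cvemp", "version": __version__, "seed": config.seed,
        "config": config.to_dict(), "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
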