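"""Serialization: trial datasets (CSV), design descriptions and study
configurations (YAML), analysis/classification reports (JSON), fixtures."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .design import ClusteringSourceSpec, IgnorabilityVerdict, classify_source
from .estimators import AnalysisResult
from .simulate import Scenario, simulate_trial, validate_dataset
from .study import DEFAULT_DESIGNS, DEFAULT_ICCS, DEFAULT_MECHANISMS, StudyTable

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_design",
    "classification_report",
    "render_report_text",
    "analysis_to_json",
    "StudyConfig",
    "load_study_config",
    "write_study_table",
    "make_fixtures",
]


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a patient-level dataset as CSV (header patient_id,arm,cluster_id,outcome)."""
    validate_dataset(df)
    # %.17g round-trips any double exactly
    df.to_csv(path, index=False, columns=["patient_id", "arm", "cluster_id", "outcome"], float_format="%.17g")


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient-level dataset CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_dataset(df)


_TIMING_ALIASES = {
    "pre": "pre_randomisation",
    "post": "post_randomisation",
    "pre_randomisation": "pre_randomisation",
    "post_randomisation": "post_randomisation",
}


def read_design(path: str | Path) -> List[ClusteringSourceSpec]:
    """Read a trial-design description (list of clustering sources) from YAML.

    Each source has keys ``name``, ``timing`` (pre/post), ``icc`` (zero /
    nonzero / unknown), and either ``used_in_randomisation`` (pre, with
    optional ``balancing``) or ``arm_assignment`` (post).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sources = doc["sources"] if isinstance(doc, dict) else doc
    specs = []
    for src in sources:
        timing = _TIMING_ALIASES.get(str(src["timing"]).lower())
        if timing is None:
            raise ValueError(f"source {src.get('name')!r}: unknown timing {src['timing']!r}")
        kwargs = dict(
            name=str(src["name"]),
            timing=timing,
            icc_assumption=str(src.get("icc", "unknown")),
        )
        if "used_in_randomisation" in src:
            kwargs["used_in_randomisation"] = bool(src["used_in_randomisation"])
        if "arm_assignment" in src:
            kwargs["arm_assignment"] = str(src["arm_assignment"])
        if "balancing" in src:
            kwargs["balancing"] = str(src["balancing"])
        specs.append(ClusteringSourceSpec(**kwargs))
    return specs


def classification_report(specs: Sequence[ClusteringSourceSpec]) -> Dict:
    """Classify every source and assemble a JSON-ready report."""
    items = []
    for spec in specs:
        verdict = classify_source(spec)
        items.append({"source": spec.name, "timing": spec.timing, **dataclasses.asdict(verdict)})
    n_non = sum(1 for it in items if it["status"] == "non_ignorable")
    return {
        "sources": items,
        "n_sources": len(items),
        "n_non_ignorable": n_non,
    }


def render_report_text(report: Dict) -> str:
    """Human-readable classification report."""
    lines = []
    for it in report["sources"]:
        lines.append(f"{it['source']} ({it['timing'].replace('_', '-')}): {it['status'].replace('_', '-')}")
        lines.append(f"  assignment correlation: {it['assignment_correlation_sign']}; "
                     f"SE bias: {it['se_bias_direction']}; type I error: {it['type1_consequence']}")
        lines.append(f"  {it['rationale']}")
    lines.append(
        f"{report['n_non_ignorable']} of {report['n_sources']} sources are non-ignorable "
        "and must be accounted for in the analysis."
    )
    return "\n".join(lines)


def analysis_to_json(result: AnalysisResult) -> str:
    return json.dumps(
        {
            "method": result.method,
            "estimate": result.beta_hat,
            "se": result.se,
            "df": result.df,
            "t": result.t_stat,
            "p": result.p_value,
        },
        indent=2,
    )


@dataclass(frozen=True)
class StudyConfig:
    """Scenario-grid configuration for a study run; defaults are the full grid."""

    designs: Tuple[Tuple[int, int], ...] = DEFAULT_DESIGNS
    iccs: Tuple[float, ...] = DEFAULT_ICCS
    mechanisms: Tuple[str, ...] = DEFAULT_MECHANISMS
    reps: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def grid(self) -> List[Scenario]:
        return [
            Scenario(n_clusters=j, n_patients=n, icc=icc, mechanism=mech, seed=self.seed)
            for (j, n) in self.designs
            for icc in self.iccs
            for mech in self.mechanisms
        ]


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a study configuration from YAML; omitted keys take the defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "designs" in doc:
        kwargs["designs"] = tuple((int(j), int(n)) for j, n in doc["designs"])
    if "iccs" in doc:
        kwargs["iccs"] = tuple(float(v) for v in doc["iccs"])
    if "mechanisms" in doc:
        kwargs["mechanisms"] = tuple(str(m) for m in doc["mechanisms"])
    for key in ("reps", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    if "alpha" in doc:
        kwargs["alpha"] = float(doc["alpha"])
    return StudyConfig(**kwargs)


def write_study_table(study: StudyTable, path: str | Path) -> None:
    study.table.to_csv(path, index=False)


_FASTER_DESIGN = {
    "trial": "FASTER",
    "sources": [
        {
            "name": "recruiting centre",
            "timing": "pre_randomisation",
            "icc": "nonzero",
            "used_in_randomisation": False,
        },
        {
            "name": "surgeon",
            "timing": "pre_randomisation",
            "icc": "nonzero",
            "used_in_randomisation": True,
        },
        {
            "name": "type of surgery",
            "timing": "pre_randomisation",
            "icc": "nonzero",
            "used_in_randomisation": True,
        },
        {
            "name": "rehabilitation class",
            "timing": "post_randomisation",
            "icc": "nonzero",
            "arm_assignment": "single_arm",
        },
    ],
}


def make_fixtures(outdir: str | Path, seed: int = 0) -> Dict[str, Path]:
    """Write small deterministic fixtures: one dataset CSV per assignment
    mechanism plus a pre-randomised blocked trial, the FASTER-style design
    YAML, and a miniature study configuration.

    Returns a mapping from fixture name to path.  Same seed, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for i, mech in enumerate(DEFAULT_MECHANISMS):
        sc = Scenario(n_clusters=4, n_patients=24, icc=0.10, mechanism=mech, seed=seed + i)
        p = outdir / f"trial_{mech}.csv"
        write_dataset(simulate_trial(sc), p)
        paths[mech] = p
    sc = Scenario(
        n_clusters=4, n_patients=24, icc=0.10, mechanism="pre_blocks", block_size=2, seed=seed + 7
    )
    p = outdir / "trial_pre_blocks.csv"
    write_dataset(simulate_trial(sc), p)
    paths["pre_blocks"] = p
    design_path = outdir / "faster_design.yaml"
    with open(design_path, "w") as fh:
        yaml.safe_dump(_FASTER_DESIGN, fh, sort_keys=False)
    paths["design"] = design_path
    config_path = outdir / "mini_study.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "designs": [[10, 100]],
                "iccs": [0.0, 0.10],
                "mechanisms": list(DEFAULT_MECHANISMS),
                "reps": 200,
                "alpha": 0.05,
                "seed": seed,
            },
            fh,
            sort_keys=False,
        )
    paths["study_config"] = config_path
    return paths
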