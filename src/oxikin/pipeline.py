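"""Multi-stage analysis pipeline with a machine-readable report.

A YAML/dict config names the stages to run (bde, rancimat, dsc, scavenge)
and their input CSVs. Every report embeds the conventions block (gas
constant, abscissa, hartree factor, ln(kB/h)) and a SHA-256 digest of each
input file, so any number in the report is traceable to its inputs and the
constants used to compute it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__, constants, dsc, rancimat, scavenging, thermochem
from .io import read_table

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("bde", "rancimat", "dsc", "scavenge")


class PipelineConfigError(ValueError):
    pass


@dataclass
class AnalysisReport:
    version: str
    conventions: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_dict(fit) -> dict:
    return {k: v for k, v in dataclasses.asdict(fit).items() if v is not None}


def run_pipeline(config: dict, base_dir: str | Path = ".") -> AnalysisReport:
    """Execute the configured stages in order and return the report.

    Config shape::

        stages:
          bde:      {species: species.csv, parent: CA, hydrogen: H-atom}
          rancimat: {ip: ip.csv, eyring: true, ln_kb_over_h: 21.46}
          dsc:      {peaks: peaks.csv, method: both}
          scavenge: {curve: curve.csv, method: interpolate}
    """
    base = Path(base_dir)
    stages = config.get("stages")
    if not stages:
        raise PipelineConfigError("config must name at least one stage under 'stages'")
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise PipelineConfigError(
            f"unknown stage(s) {sorted(unknown)}; known: {list(KNOWN_STAGES)}")

    report = AnalysisReport(version=__version__, conventions=constants.conventions())

    def load(stage: str, key: str, schema: str):
        try:
            rel = stages[stage][key]
        except (KeyError, TypeError):
            raise PipelineConfigError(f"stage {stage!r}: missing input {key!r}") from None
        path = base / rel
        df = read_table(path, schema)
        report.input_digests[str(rel)] = _digest(path)
        return df

    # stages run in canonical order regardless of dict ordering
    for stage in (s for s in KNOWN_STAGES if s in stages):
        opts = stages[stage] or {}
        logger.info("running stage %s", stage)
        if stage == "bde":
            species = load(stage, "species", "species")
            table = thermochem.bde_table(
                species, opts.get("parent", "CA"), opts.get("hydrogen", "H-atom"))
            report.results["bde"] = table.to_dict(orient="records")
        elif stage == "rancimat":
            ip = load(stage, "ip", "induction_period")
            rates = rancimat.rate_constants(ip)
            fits = []
            for sample in rates["sample"].unique():
                fits.append(_fit_dict(rancimat.arrhenius_fit(rates, sample)))
                if opts.get("eyring", True):
                    fits.append(_fit_dict(rancimat.eyring_fit(
                        rates, sample,
                        ln_kb_over_h=float(opts.get(
                            "ln_kb_over_h", constants.LN_KB_OVER_H_DEFAULT)))))
            report.results["rancimat"] = fits
        elif stage == "dsc":
            peaks = load(stage, "peaks", "dsc_peaks")
            method = opts.get("method", "both")
            methods = ("fwo", "kas") if method == "both" else (method,)
            fits = []
            for sample in peaks["sample"].unique():
                for m in methods:
                    fitter = dsc.fwo_fit if m == "fwo" else dsc.kas_fit
                    fits.append(_fit_dict(fitter(peaks, sample)))
            report.results["dsc"] = fits
        elif stage == "scavenge":
            curve = load(stage, "curve", "dose_response")
            curve = scavenging.add_scavenging_rates(curve)
            result = {
                "assay": curve["assay"].iloc[0],
                "sr_percent": curve["sr_percent"].tolist(),
                "ic50_ug_ml": scavenging.ic50(
                    curve, method=opts.get("method", "interpolate")),
                "ic50_method": opts.get("method", "interpolate"),
            }
            report.results["scavenge"] = result
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Write report.json plus one TSV summary per fitting stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(report.to_json() + "\n")
    import pandas as pd

    for stage in ("rancimat", "dsc", "bde"):
        if stage in report.results:
            pd.DataFrame(report.results[stage]).to_csv(
                out / f"{stage}_summary.tsv", sep="\t", index=False)
    return json_path
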