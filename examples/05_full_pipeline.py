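"""End-to-end run: generate every input, execute the full pipeline, summarise.

Writes a synthetic fixture bundle (qPCR CSV, feature table, taxonomy, tree,
metadata, SCFA table), builds a run configuration and executes
quantify -> predict -> engraft -> diversity -> scfa.  The JSON report is
fully deterministic for a fixed seed: repeat runs are byte-identical.
"""

import tempfile
from pathlib import Path

from gutwash import SynthConfig
from gutwash.io import load_config, run_pipeline, write_synth_fixtures

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    paths = write_synth_fixtures(SynthConfig(seed=42), tmp / "fixtures")
    cfg_file = tmp / "run.yaml"
    inputs = "\n".join(f"  {k}: {v}" for k, v in paths.items())
    cfg_file.write_text(f"seed: 42\ninputs:\n{inputs}\n")

    report = run_pipeline(load_config(cfg_file), outdir=tmp / "out")

    print("stages:", ", ".join(report["stages"]))
    for br in report["stages"]["engraft"]["bioreplicates"]:
        calls = {
            s["compartment"]: s["classification"]
            for s in br["series"] if s["phase"] == "lumen"
        }
        print(f"{br['bioreplicate']} luminal classifications: {calls}")
    div = report["stages"]["diversity"]
    print("mean Shannon by region:",
          {k: round(v, 2) for k, v in div["mean_alpha_by_region"]["shannon"].items()})
    scfa = report["stages"]["scfa"]
    print(f"SCFA pre/post tests: {scfa['n_significant']} of "
          f"{scfa['n_pairs_tested']} strata significant")
    print("\n(the default generator grows the organism in the AC at 1.2x/cycle;"
          "\n every luminal series therefore exceeds the pure-washout null, and the"
          "\n fitted per-compartment multipliers in report.json separate AC growth"
          "\n from the net death downstream)")
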