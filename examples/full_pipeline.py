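"""Run the whole configured pipeline and inspect its manifest.

Equivalent to `cogmaturity run --outdir out --seed 42` with a reduced cohort:
simulate -> exclude -> score -> CFA/SEM -> age model -> CMI report, with every
output file checksummed in manifest.json.
"""

import json
import tempfile
import warnings
from pathlib import Path

from cogmaturity import pipeline
from cogmaturity.cohort import CohortConfig

warnings.filterwarnings("ignore", category=UserWarning)

outdir = Path(tempfile.mkdtemp(prefix="cogmaturity_"))
cfg = pipeline.PipelineConfig(cohort=CohortConfig(n_participants=60), seed=42)
manifest = pipeline.run_pipeline(cfg, outdir)

print("stage counts:", json.dumps(manifest["counts"], indent=2))
print("\nage model:", json.dumps(
    {k: v for k, v in manifest["stages"]["fit-age"].items() if k != "seconds"}, indent=2))
print(f"\n{len(manifest['files'])} files written to {outdir} (see manifest.json for checksums)")
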