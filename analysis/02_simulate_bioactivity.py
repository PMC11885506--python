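#!/usr/bin/env python
"""Generate the synthetic bioactivity study standing in for lab readouts.

Builds a two-readout study for one test material: a barrier-integrity-like
readout with a strong, late-onset concentration-dependent effect (the kind
of response a fibrogenic aerosol produces) and a cytokine-like readout with
no effect (a null readout for calibration).  The known ground-truth
detectability thresholds are recorded alongside.  Outputs land in
results/datasets/.
"""

import json
from pathlib import Path

from respirisk.synthetic import (ResponseSurfaceSpec, SyntheticStudySpec,
                                 generate_bioactivity, ground_truth_pod)

OUT = Path(__file__).resolve().parent.parent / "results" / "datasets"

STUDY = {
    "teer": ResponseSurfaceSpec(amplitude=2.0, ec50=1.0, hill=2.0,
                                onset_day=2.0, noise_sd=0.1,
                                direction="decrease"),
    "il8": ResponseSurfaceSpec(amplitude=0.0, noise_sd=0.1),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = {}
    for readout, surface in STUDY.items():
        spec = SyntheticStudySpec(
            materials=(("benchmark", surface),),
            concentrations=(0.1, 1.0, 10.0), n_replicates=3, seed=1,
            readout=readout)
        ds = generate_bioactivity(spec)
        path = OUT / f"{readout}.csv"
        ds.to_csv(path)
        gt = ground_truth_pod(spec, "benchmark")
        truth[readout] = gt
        print(f"{readout}: wrote {path.name} "
              f"(ground-truth detectable from "
              f"{'never' if gt is None else f'{gt:.3g} ug/cm2'})")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


if __name__ == "__main__":
    main()
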