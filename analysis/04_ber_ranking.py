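#!/usr/bin/env python
"""Combine exposure predictions and PoDs into the BER risk ranking.

Divides the lowest concentration-dependent PoD (from 03_fit_pod.py) by the
worst-case regional exposure of every scenario (from
01_dosimetry_scenarios.py) and flags scenarios whose minimum BER falls
below 1.  Outputs land in results/ber/.
"""

from pathlib import Path

from respirisk.pipeline import PipelineConfig, run_ber

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = PipelineConfig(outdir=ROOT, seed=1)
    table = run_ber(config)
    print("\nBER ranking (ascending; BER < 1 flagged as potential risk):")
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.3g}"))
    flagged = table.loc[table["flagged"] == True, "scenario"]  # noqa: E712
    print(f"\nflagged scenarios: {', '.join(flagged) if len(flagged) else 'none'}")


if __name__ == "__main__":
    main()
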