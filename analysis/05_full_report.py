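#!/usr/bin/env python
"""End-to-end pipeline run: cohort + simulated images + all report tables.

Drives :func:`hfuscad.cohort.run_pipeline` with images attached (one
simulated frame per animal at its severity-class grade) and writes the full
report bundle (cohort table, screening, correlations, cross-tabs,
normalized-feature summary) under results/report/.
"""

from pathlib import Path

from hfuscad.cohort import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "report"


def main():
    report = run_pipeline(seed=0, with_images=True, out_dir=OUT)
    print((OUT / "summary.txt").read_text())
    print(report["correlations"].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
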