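#!/usr/bin/env python
"""Full synthetic-cohort connectivity analysis: simulate, map, cluster.

Runs the end-to-end pipeline on the default desk-scale cohort (three groups
of nine subjects, two runs of 185 volumes each, 32x32x16 grid of 2 mm
voxels): per-subject seed-connectivity z maps for the left and right
hippocampus seeds, random-effects one-sample (intragroup) and pooled
two-sample (intergroup) t maps, Bonferroni voxel thresholding at p<0.001,
and 1 cm^3 cluster-extent filtering.

Imaging outputs (NIfTI t maps) land under scratch/; the cluster tables and
the symmetry counts are copied to results/. With the default planted
couplings the intragroup maps peak inside the seed's ipsilateral network
(peak t well above the t>15 display threshold) and every intergroup
contrast favours the less-impaired group.
"""

import shutil
from pathlib import Path

from hippofc.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort_maps"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = run_pipeline(PipelineConfig(rng_seed=0), out_dir=SCRATCH)

    for rel in manifest["artifacts"]["cluster_tables"]:
        shutil.copy(SCRATCH / rel, RESULTS / rel)
    for rel in manifest["artifacts"]["symmetry"]:
        shutil.copy(SCRATCH / rel, RESULTS / rel)

    print((SCRATCH / "symmetry_report.txt").read_text())
    import pandas as pd

    for seed in ("left", "right"):
        table = pd.read_csv(
            SCRATCH / f"clusters_tmap_{seed}_seed_control.tsv", sep="\t"
        )
        if len(table):
            top = table.iloc[0]
            print(
                f"{seed} seed, control group: peak t = {top.peak_t:.2f} at "
                f"({top.peak_x_mm:.0f}, {top.peak_y_mm:.0f}, {top.peak_z_mm:.0f}) mm, "
                f"cluster of {top.size_vox} voxels ({top.size_cm3:.2f} cm^3)"
            )


if __name__ == "__main__":
    main()
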