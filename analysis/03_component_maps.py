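#!/usr/bin/env python
"""Report the component maps: scale each source to a z-map, threshold at
|z| > 3.0, list 26-connected clusters of at least 0.1 cc with side, volume,
peak |z| and peak coordinate, and flag boundary-artifact candidates.

Reads scratch/decomposition/, writes results/tables/component_clusters.tsv
and per-component z-maps (NIfTI) under scratch/zmaps/.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    from hipposbm.maps import component_report, report_table
    from hipposbm.volume_io import read_mask, scatter_to_volume, write_volume

    dec_path = ROOT / "scratch" / "decomposition" / "decomposition.npz"
    if not dec_path.exists():
        raise SystemExit("no decomposition found; run analysis/02_decompose.py first")
    S = np.load(dec_path)["S"]
    mask = read_mask(ROOT / "scratch" / "simulated" / "roi_mask.nii.gz")

    # the synthetic Gaussian bumps yield ~0.04-0.07 cc suprathreshold
    # clusters, below the 0.1 cc floor used for real data, so this driver
    # reports at 0.03 cc (the pipeline default remains 0.1 cc)
    reports = [component_report(k, S[k], mask, min_report_cc=0.03) for k in range(S.shape[0])]
    table = report_table(reports)
    out = ROOT / "results" / "tables" / "component_clusters.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)

    zdir = ROOT / "scratch" / "zmaps"
    zdir.mkdir(parents=True, exist_ok=True)
    for rep in reports:
        write_volume(scatter_to_volume(rep.z_map, mask), zdir / f"component_{rep.component:02d}_z.nii.gz")

    print(table.to_string(index=False))
    for rep in reports:
        tag = "ARTIFACT?" if rep.artifact_flag else "ok"
        print(
            f"component {rep.component}: {len(rep.clusters)} clusters >= "
            f"{rep.min_report_cc} cc [{tag}]"
        )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
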