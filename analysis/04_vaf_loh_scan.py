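#!/usr/bin/env python
"""Windowed VAF track at reference-heterozygous positions and the LOH
scan, for every specimen of the simulated cohort (expected clean), then
for one specimen with an injected LOH segment (expected flagged)."""

from pathlib import Path

import numpy as np
import pandas as pd

from clonalpop import synthdata as sd
from clonalpop import vafloh as vl
from clonalpop import variants as va

RESULTS = Path(__file__).resolve().parent.parent / "results"
OUT = RESULTS / "vafloh"
SEED = 20_260_921
SPEC = dict(
    n_populations=2, samples_per_population=(10, 5), n_sites=30_000,
    private_snvs_per_population=1500, private_snvs_per_sample=120,
    shared_snvs_all=2500, reference_het_fraction=0.25, seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = sd.generate_reference_profile(30_000, 0.25, seed=SEED)
    cfg = vl.VafConfig(window_size=1000)
    het = vl.select_het_positions(ref, cfg)
    sites = va.read_vcf(RESULTS / "simulated" / "cohort.vcf")

    truth, _ = sd.generate_clonal_genotypes(sd.PopulationSpec(**SPEC), ref)
    frames = []
    flagged = 0
    for sid in truth.sample_ids:
        arrays = vl.sample_read_arrays(sites, sid, ref, het)
        scan = vl.loh_scan(vl.windowed_vaf(sid, *arrays, cfg), cfg)
        flagged += int(scan["flagged"].sum())
        frames.append(scan)
    pd.concat(frames).to_csv(OUT / "vaf_track.tsv", sep="\t", index=False)
    print(f"{het.size} reference-het positions in windows of {cfg.window_size}; "
          f"{len(frames[0])} windows per specimen")
    print(f"clean cohort: {flagged} flagged windows across {truth.n_samples} specimens")

    # inject LOH over the first full window of one specimen and rescan
    span = (0, int(het[cfg.window_size - 1]) + 1)
    modified, report = sd.inject_loh(truth, ref, "P1_S1", span)
    rng = np.random.default_rng(SEED)
    row = modified.dosage[modified.sample_ids.index("P1_S1")]
    depths = rng.poisson(40, size=het.size).clip(min=1).astype(float)
    alt = rng.binomial(depths.astype(int), row[het] / 3.0).astype(float)
    scan = vl.loh_scan(
        vl.windowed_vaf("P1_S1+LOH", ref.contigs[het], ref.positions[het],
                        alt, depths, ref.dosage[het], cfg),
        cfg,
    )
    scan.to_csv(OUT / "vaf_track_injected.tsv", sep="\t", index=False)
    w0 = scan.iloc[0]
    print(f"injected LOH over {len(report)} het sites: window 1 mean VAF "
          f"{w0['mean_vaf']:.3f} vs expected {w0['expected_vaf']:.3f} "
          f"-> flagged={bool(w0['flagged'])}; "
          f"{int(scan['flagged'].sum())} window(s) flagged in total")


if __name__ == "__main__":
    main()
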