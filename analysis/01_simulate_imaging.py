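"""Generate the simulated imaging cohort: per-animal phantom stacks.

Creates 10 wild-type and 10 knockout phantom reflectance stacks (the
knockout group's responsive region is larger and stronger) and writes them,
with ground-truth amplitude maps and config sidecars, under scratch/imaging/.
A small manifest goes to results/.
"""

import json
from pathlib import Path

from barrelcross.cohort import imaging_cohort_configs
from barrelcross.io import write_stack
from barrelcross.phantom import generate_ois_stack

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "imaging"
SEED = 1


def main() -> None:
    configs = imaging_cohort_configs(n_wt=10, n_ko=10, seed=SEED)
    manifest = []
    for i, (genotype, cfg) in enumerate(configs):
        ph = generate_ois_stack(cfg)
        name = f"{genotype.lower()}_{i:02d}.tif"
        write_stack(OUT / name, ph.stack, truth=ph.truth, config=cfg)
        manifest.append(
            {"file": name, "genotype": genotype, "peak_drr": cfg.peak_drr,
             "blob_sigma": cfg.blob_sigma, "seed": cfg.seed}
        )
        print(f"{name}: {genotype}, peak dR/R {cfg.peak_drr:.2e}, sigma {cfg.blob_sigma:.2f} px")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "imaging_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"\nwrote {len(manifest)} phantom stacks to {OUT}")


if __name__ == "__main__":
    main()
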