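"""Generate the synthetic study bundle all later analysis steps consume.

Writes TPS landmark files (bumblebee fore-/hindwings, ant heads of two
species, plus replicated error-study sets), genotype CSVs, and the
pooled body-burden and membership tables to results/study/.  The
layout mirrors the published sampling design: 64 + 4 bumblebees across
two alpine locations, 115 + 89 ants of two species spread over nests,
six pooled chemical samples.
"""
import pathlib
import warnings

from asymlink.simulate import make_study

SEED = 20180901  # sampling campaign date used as the study seed
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "study"


def main():
    warnings.filterwarnings("ignore")
    bundle = make_study(seed=SEED, out_dir=OUT)
    print(f"wrote study bundle to {OUT}")
    print(f"  bumblebees: {len(bundle.genotypes_bees.individuals)} individuals, "
          f"{len(bundle.forewings)} forewing + {len(bundle.hindwings)} hindwing configs")
    for species, ds in bundle.heads.items():
        print(f"  {species}: {len(ds)} head configs")
    print(f"  pools: {bundle.membership['pool_id'].nunique()}, "
          f"members: {len(bundle.membership)}")


if __name__ == "__main__":
    main()
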