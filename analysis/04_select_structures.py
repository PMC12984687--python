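#!/usr/bin/env python
"""Derive and report the pruned recursive structures from the FRM posterior.

Applies the two pruning rules to the fully recursive fit: the 1.96
signal-to-noise rule on residual structural coefficients (REC1) and the 0.15
absolute-magnitude rule on both sides (REC2); writes the resulting masks as
a YAML fragment usable as a model-roster override, plus a removal report.
"""

import argparse
from pathlib import Path

import yaml

from semsire import load_samples, rec1_mask, rec2_mask
from semsire.config import masks_to_yaml_fragment
from semsire.cov_structures import full_mask
from semsire.structure_selection import removal_report, summaries_from_samples


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--frm", type=Path, default=Path("results/fits/FRM"))
    parser.add_argument("--out", type=Path, default=Path("results/selected_masks.yaml"))
    args = parser.parse_args()

    frm = load_samples(args.frm)
    labels = frm.trait_labels
    p = len(labels)
    gsum = summaries_from_samples(frm.g_native["pi"], "G")
    rsum = summaries_from_samples(frm.r_native["pi"], "R")
    mask_r1 = rec1_mask(rsum, p)
    mask_g2, mask_r2 = rec2_mask(gsum, rsum, p)

    models = {}
    models.update(masks_to_yaml_fragment("REC1", full_mask(p), mask_r1))
    models.update(masks_to_yaml_fragment("REC2", mask_g2, mask_r2))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(yaml.safe_dump({"models": models}, sort_keys=False))

    for title, mask, side in (
        ("REC1 (signal rule, residual side)", mask_r1, "residual"),
        ("REC2 (magnitude rule, genetic side)", mask_g2, "genetic"),
        ("REC2 (magnitude rule, residual side)", mask_r2, "residual"),
    ):
        lines = removal_report(mask, labels, side)
        print(f"{title}: {len(lines)} paths fixed to zero")
        for line in lines:
            print(" ", line)
    print("masks written to", args.out)


if __name__ == "__main__":
    main()
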