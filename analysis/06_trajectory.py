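"""Monocyte LPS-response trajectory: pseudotime, activation states, peaks.

Embeds baseline + LPS monocytes on the PCs of their differentially induced
features, fits a principal curve (pseudotime = arc length from the
baseline end), partitions the trajectory with k-means (k = 4) into
Baseline/LPS1/LPS2/LPS3 states ordered by mean pseudotime, reports genes
uniquely induced per state, and the pseudotime at which each induced gene's
smoothed expression peaks.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from citemux import destats as ds
from citemux import surface as sf
from citemux import trajectory as tj
from citemux.config import PipelineConfig, Seeds
from citemux.io import read_multimodal


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--exp-dir", type=Path,
                    default=Path("results/experiment"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--cell-type", default="CD14_monocyte")
    ap.add_argument("--condition", default="LPS")
    args = ap.parse_args()

    counts = read_multimodal(args.exp_dir / "counts")
    ann = pd.read_csv(args.out_dir / "cell_annotations.tsv", sep="\t")
    cells = ann.loc[~ann["multiplet_flag"]].reset_index(drop=True)
    sub = counts.subset(pd.Index(cells["barcode"]))

    cfg = PipelineConfig(seeds=Seeds.from_base(args.seed))
    lognorm = ds.lognormalize(sub.rna, scale=cfg.lognorm_scale)
    clr = sf.clr_normalize(sub.adt, pseudocount=cfg.clr_pseudocount)
    joint = sp.vstack([lognorm, sp.csr_matrix(clr)]).tocsr()
    names = list(sub.gene_names) + list(sub.adt_names)

    de = pd.read_csv(args.out_dir
                     / f"de_{args.cell_type}_{args.condition}.tsv", sep="\t")
    de_feats = de.loc[de["significant"], "feature"].tolist()

    mask = ((cells["cell_type"] == args.cell_type)
            & cells["condition"].isin(["baseline", args.condition]))
    idx = np.flatnonzero(mask.to_numpy())
    is_base = cells.loc[mask, "condition"].to_numpy() == "baseline"
    pt, emb = tj.infer_pseudotime(joint[:, idx], names, de_feats, is_base,
                                  config=cfg)
    states = tj.kmeans_states(emb, pt, k=cfg.kmeans_k,
                              seed=cfg.seeds.trajectory,
                              state_prefix=args.condition)

    traj = pd.DataFrame({"barcode": cells.loc[mask, "barcode"].to_numpy(),
                         "condition": cells.loc[mask, "condition"].to_numpy(),
                         "pseudotime": pt, "state": states.to_numpy()})
    traj.to_csv(args.out_dir / "trajectory.tsv", sep="\t", index=False)
    print(traj.groupby("state")["pseudotime"]
          .agg(["mean", "count"]).round(2).to_string())

    markers = tj.state_marker_genes(joint[:, idx], names, states, config=cfg)
    pd.DataFrame([{"state": s, "feature": g}
                  for s, gs in markers.items() for g in gs]).to_csv(
        args.out_dir / "state_markers.tsv", sep="\t", index=False)
    print("uniquely induced per state:",
          {s: len(g) for s, g in markers.items()})

    induced = de.loc[de["significant"] & (de["direction"] == "up"),
                     "feature"]
    dense = np.asarray(joint[:, idx].todense())
    name_idx = pd.Index(names)
    peaks = pd.DataFrame(
        [{"feature": g,
          "peak_pseudotime": tj.peak_time(
              dense[name_idx.get_loc(g)], pt,
              bandwidth_frac=cfg.peak_bandwidth_frac)} for g in induced])
    peaks.to_csv(args.out_dir / "peaks.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
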