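"""Run the first factorial experiment (no destination bias).

Crosses the 7 resistance surfaces with the 7 movement-mechanism combinations,
focal scales, focal functions and autocorrelation levels, simulates the
density-of-movement truth for each scenario, scores the three connectivity
models against it, and appends everything to a long-format scenario table.

The default reduced profile (64x64 grid, 25 sources, 100 paths per source,
scale fixed at 1x1 focal mean) finishes in minutes; --profile full runs the
published-scale grid (256x256, 100 sources, all scales; hours).
"""

import argparse

from landconn.pipeline import ExperimentConfig, run_experiment, summarize_by_model


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--profile", choices=["reduced", "desk", "full"], default="reduced")
    ap.add_argument("--seed", type=int, default=0, help="master seed")
    ap.add_argument("--out", default="results/first_scenarios.csv")
    args = ap.parse_args()

    if args.profile == "full":
        cfg = ExperimentConfig.preset("full", analysis_id="first", master_seed=args.seed)
    elif args.profile == "desk":
        cfg = ExperimentConfig.preset("desk", analysis_id="first", master_seed=args.seed)
    else:  # reduced: desk grid, full replication, scale slice
        cfg = ExperimentConfig.preset(
            "desk", analysis_id="first", master_seed=args.seed,
            paths_per_source=100, scale_ns=(1,), scale_fns=("mean",),
        )
    table = run_experiment(cfg, table_path=args.out, progress=True)
    print(f"\n{len(table)} scenario-model rows -> {args.out}")
    print("pooled accuracy by model:")
    print(summarize_by_model(table).round(4).to_string())


if __name__ == "__main__":
    main()
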