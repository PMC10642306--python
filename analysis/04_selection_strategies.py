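"""Compare clone-selection strategies with the FAI-BLUP index.

Builds the genotype x (trait, season) BLUP matrices for the clone-only
vectors (u_c' from METMwF, u_c from METMpF) and the total genotypic
vector (u_g), ranks each with the factor-analytic ideotype index
(3 factors for the 6 variables), and reports the top-20% Czekanowski
overlap and Spearman correlation between the strategies, plus the FAI
communalities.  Reads the met_* tables written by 03 if present,
otherwise recomputes them.
"""

from pathlib import Path

from clonesel.pipeline import PipelineConfig, run_met_study, write_report

SEED = 1


def main() -> None:
    cfg = PipelineConfig(seed=SEED, n_factors=3)
    report = run_met_study(cfg)
    write_report(report, Path("results"))
    print(report.tables["met_fai"].to_string(index=False))
    print()
    print(report.tables["met_selection"].to_string(index=False))


if __name__ == "__main__":
    main()
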