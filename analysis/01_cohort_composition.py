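#!/usr/bin/env python
"""Cohort composition and ethnic-group sharing arithmetic.

Recomputes, from the packaged composition table, the non-African share of
the combined modern cohort (88.5% of 251,214 individuals) and the
ethnic-group shared fractions between the European and East Asian variant
sets (140 shared variants are 23% of the 620 European and 45% of the 313
East Asian variants). Writes results/cohort_composition.tsv.
"""

from pathlib import Path

from pvarch.fixtures import load_nonafrican_composition
from pvarch.pv_extraction import round_half_up
from pvarch.sharing_analysis import shared_fraction

OUT = Path(__file__).resolve().parent.parent / "results"

N_AFRICAN = 28_872  # published African cohort size


def main() -> None:
    comp = load_nonafrican_composition()
    n_nonafrican = int(comp["cases"].sum())
    total = n_nonafrican + N_AFRICAN
    share = round_half_up(100.0 * n_nonafrican / total)
    print(f"non-African cohort: {n_nonafrican:,} of {total:,} individuals ({share}%)")

    eu_shared = shared_fraction(140, 620)
    ea_shared = shared_fraction(140, 313)
    print(f"140 shared variants = {eu_shared}% of European (620), "
          f"{ea_shared}% of East Asian (313)")

    OUT.mkdir(exist_ok=True)
    comp.to_csv(OUT / "cohort_composition.tsv", sep="\t", index=False)
    with open(OUT / "cohort_shares.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"nonafrican_individuals\t{n_nonafrican}\n")
        fh.write(f"african_individuals\t{N_AFRICAN}\n")
        fh.write(f"nonafrican_percent\t{share}\n")
        fh.write(f"european_shared_percent\t{eu_shared}\n")
        fh.write(f"east_asian_shared_percent\t{ea_shared}\n")
    print(f"wrote {OUT / 'cohort_composition.tsv'} and {OUT / 'cohort_shares.tsv'}")


if __name__ == "__main__":
    main()
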