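"""How much clonal diversity can a given DNA input even contain?

Computes the rearrangement ceiling for a two-replicate, 50 ng B-cell
equivalent amplification, the cells-per-nanogram rule of thumb, and the
input DNA needed when only 35% of the cells are B cells.
"""

from clonescape import cells_per_ng, input_dna_for_b_cells, max_rearrangements

ng = 50 * 2  # two replicates of 50 ng B-cell-equivalent gDNA
print(f"max rearrangements from {ng} ng B-cell DNA: {max_rearrangements(ng):,}")
print(f"cells per ng of pure B-cell DNA: ~{cells_per_ng()}")
print(f"input DNA for 50 ng B-cell equivalents at 35% B cells: "
      f"{input_dna_for_b_cells(50, 0.35)} ng")
print()
print("If a library reports far more unique sequences than the first number,")
print("suspect sequencing error; far fewer, suspect a poor sample or filter.")
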