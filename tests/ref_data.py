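"""Verbatim reference listings for the two bundled demo instances.

The 2x3 walk-through instance (costs [[2,4,1],[1,2,3]]) has published
intermediate tube listings: the 36 feasible assignment strands after the
individual filter and the 6 shortest weighted strands that spell the
optimum.  The 3x5 instance has a published codeword table (see
``dnassign/data/demo_code.fasta``), the 15 edge-strand sequences it
induces, and the 125-base solution strand.
"""

# The 36 strands surviving the job and individual filters for the 2x3
# instance: every job exactly once, both individuals used.
FEASIBLE_2X3 = [
    "sA1eB1sA1eB2sA2eB3", "sA1eB1sA1eB3sA2eB2", "sA1eB1sA2eB2sA1eB3",
    "sA1eB1sA2eB2sA2eB3", "sA1eB1sA2eB3sA1eB2", "sA1eB1sA2eB3sA2eB2",
    "sA1eB2sA1eB1sA2eB3", "sA1eB2sA1eB3sA2eB1", "sA1eB2sA2eB1sA1eB3",
    "sA1eB2sA2eB1sA2eB3", "sA1eB2sA2eB3sA1eB1", "sA1eB2sA2eB3sA2eB1",
    "sA1eB3sA1eB1sA2eB2", "sA1eB3sA1eB2sA2eB1", "sA1eB3sA2eB1sA1eB2",
    "sA1eB3sA2eB1sA2eB2", "sA1eB3sA2eB2sA1eB1", "sA1eB3sA2eB2sA2eB1",
    "sA2eB1sA1eB2sA1eB3", "sA2eB1sA1eB2sA2eB3", "sA2eB1sA1eB3sA1eB2",
    "sA2eB1sA1eB3sA2eB2", "sA2eB1sA2eB2sA1eB3", "sA2eB1sA2eB3sA1eB2",
    "sA2eB2sA1eB1sA1eB3", "sA2eB2sA1eB1sA2eB3", "sA2eB2sA1eB3sA1eB1",
    "sA2eB2sA1eB3sA2eB1", "sA2eB2sA2eB1sA1eB3", "sA2eB2sA2eB3sA1eB1",
    "sA2eB3sA1eB1sA1eB2", "sA2eB3sA1eB1sA2eB2", "sA2eB3sA1eB2sA1eB1",
    "sA2eB3sA1eB2sA2eB1", "sA2eB3sA2eB1sA1eB2", "sA2eB3sA2eB2sA1eB1",
]

# The 6 shortest weighted strands for the 2x3 instance: all orderings of
# the optimal edge set {(1,3), (2,1), (2,2)}, each with tail w13 w21 w22.
SOLUTION_2X3 = [
    "sA1eB3sA2eB1sA2eB2w13w21w22", "sA1eB3sA2eB2sA2eB1w13w21w22",
    "sA2eB1sA1eB3sA2eB2w13w21w22", "sA2eB1sA2eB2sA1eB3w13w21w22",
    "sA2eB2sA1eB3sA2eB1w13w21w22", "sA2eB2sA2eB1sA1eB3w13w21w22",
]

# One weighted strand listed for the 2x3 instance after weight appending.
WEIGHTED_EXAMPLE_2X3 = "sA1eB3sA2eB1sA2eB2w13w21w22"

# The published nucleotide sequences (3'->5') of the 15 edge strands
# sA_i eB_j of the 3x5 demo codeword table.
EDGE_SEQUENCES_3X5 = {
    (1, 1): "CTATCTAAAAAACTCAATTA",
    (1, 2): "CTATCTAAAAAACTCCATTA",
    (1, 3): "CTATCTAAAAAACTCATCTA",
    (1, 4): "CTATCTAAAAAACTCCAAAC",
    (1, 5): "CTATCTAAAAAACTCATCCA",
    (2, 1): "CTATCCTTTTAACTCAATTA",
    (2, 2): "CTATCCTTTTAACTCCATTA",
    (2, 3): "CTATCCTTTTAACTCATCTA",
    (2, 4): "CTATCCTTTTAACTCCAAAC",
    (2, 5): "CTATCCTTTTAACTCATCCA",
    (3, 1): "CTATCTTCAAAACTCAATTA",
    (3, 2): "CTATCTTCAAAACTCCATTA",
    (3, 3): "CTATCTTCAAAACTCATCTA",
    (3, 4): "CTATCTTCAAAACTCCAAAC",
    (3, 5): "CTATCTTCAAAACTCATCCA",
}

# The published 125-base solution strand for the 3x5 instance
# (edges sA1eB3 sA1eB4 sA2eB2 sA3eB1 sA3eB5, tail w13 w14 w22 w31 w35).
SOLUTION_SEQUENCE_3X5 = (
    "CTATCTAAAAAACTCATCTA"
    "CTATCTAAAAAACTCCAAAC"
    "CTATCCTTTTAACTCCATTA"
    "CTATCTTCAAAACTCAATTA"
    "CTATCTTCAAAACTCATCCA"
    "TTACATACCCATAATCCTTCTTAAC"
)

# The published optimum of the 3x5 instance.
OPTIMUM_3X5 = {1: 3, 2: 2, 3: 1, 4: 1, 5: 3}
OPTIMUM_COST_3X5 = 17
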