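"""Published full-depth library sizes of the eight-sample breast-cancer cohort.

Four triple-negative breast cancer (TNBC) tumors and four TNBC-free
(normal breast tissue) controls, single-end bulk RNA-seq. The per-group
read totals below are the inputs to the optimal-depth estimators: with no
saturation observed at these depths, Estimator I (average depth) and
Estimator II (largest individual depth) are lower bounds on the reads
needed for the expressed-gene count to plateau.
"""

TNBC_RUNS = ("SRR1313137", "SRR1313135", "SRR1313134", "SRR1313133")
TNBC_FREE_RUNS = ("SRR1313211", "SRR1313214", "SRR1313219", "SRR1313220")

TNBC_LIBRARY_SIZES = (34_974_017, 46_677_107, 17_574_408, 24_440_340)
TNBC_FREE_LIBRARY_SIZES = (25_900_791, 43_454_785, 31_426_867, 33_517_581)

ALL_LIBRARY_SIZES = TNBC_LIBRARY_SIZES + TNBC_FREE_LIBRARY_SIZES

#: gene count of the Entrez-based annotation used with the cohort
ANNOTATION_GENE_COUNT = 23_648
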