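"""Packaged reference data.

The benchmark table below reproduces published signed log10 p-values (SLPs)
from a UK Biobank weighted-burden comparison of variant-pathogenicity
predictors: 18 gene-phenotype pairs (hyperlipidaemia, hypertension and type
2 diabetes phenotypes) scored by a DNA language model (GPN-MSA) and the ten
other predictors with the highest average SLP.  Each gene is labelled with
the direction of association of damaging rare variants (case or control;
"control" marks protective genes whose analysis phenotype was recoded to
"being a control").  The published per-predictor averages over the 18 genes
are included so that recomputed row means can be checked against them.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "load_published_slp_table",
    "published_mean_slp",
    "load_published_gene_pairs",
]

# genes x direction x phenotype, in published column order
_GENE_INFO = """\
gene	phenotype	direction
LDLR	hyperlipidaemia	case
ABCG5	hyperlipidaemia	case
NPC1L1	hyperlipidaemia	control
PCSK9	hyperlipidaemia	control
APOC3	hyperlipidaemia	control
ANGPTL3	hyperlipidaemia	control
DNMT3A	hypertension	case
FES	hypertension	case
ASXL1	hypertension	case
SMAD6	hypertension	case
NPR1	hypertension	case
GUCY1A1	hypertension	case
INPPL1	hypertension	control
DBH	hypertension	control
GCK	type_2_diabetes	case
HNF4A	type_2_diabetes	case
HNF1A	type_2_diabetes	case
GIGYF1	type_2_diabetes	case
"""

_SLP_TABLE = """\
predictor	LDLR	ABCG5	NPC1L1	PCSK9	APOC3	ANGPTL3	DNMT3A	FES	ASXL1	SMAD6	NPR1	GUCY1A1	INPPL1	DBH	GCK	HNF4A	HNF1A	GIGYF1	published_average
GPN-MSA	16.91	1.97	0.46	2.36	0.90	1.23	-0.03	0.98	-0.94	-0.79	0.28	1.21	0.41	4.11	4.38	1.41	1.59	0.51	2.05
AlphaMissense Score	80.06	1.56	0.73	11.61	-0.15	2.59	2.97	4.34	0.32	0.44	4.15	4.40	1.41	1.84	4.36	8.24	3.72	2.11	7.48
AlphaMissense Category	76.32	1.99	0.71	9.66	-0.45	3.91	2.93	2.98	0.44	0.24	4.81	4.44	1.16	2.58	6.49	6.15	2.27	1.16	7.10
Polyphen2 HVAR rankscore	50.16	1.41	0.79	7.09	0.51	0.40	0.42	6.85	0.11	0.70	2.41	2.71	1.30	3.91	10.21	2.19	1.41	0.33	5.16
Polyphen2 HDIV rankscore	44.08	1.03	1.35	6.23	1.05	0.26	1.04	6.90	0.17	0.41	0.96	1.90	0.83	3.06	10.61	2.36	1.28	0.22	4.65
SIFT4G converted rankscore	36.24	0.34	1.49	4.84	-0.02	0.58	3.45	3.53	0.46	0.46	3.96	3.44	-0.05	5.59	11.14	3.08	0.44	0.29	4.40
MutationAssessor rankscore	45.84	1.28	1.43	6.34	0.00	1.88	1.51	1.96	-0.15	0.42	3.66	0.00	0.69	1.67	8.19	2.67	0.00	0.00	4.30
SIFT converted rankscore	27.01	1.22	1.05	10.07	0.02	1.30	0.53	4.07	-0.06	0.45	3.66	4.20	0.21	5.15	10.08	2.74	0.13	0.35	4.01
PROVEAN converted rankscore	31.41	1.06	1.39	9.75	0.40	2.03	0.48	1.72	0.33	0.11	2.49	3.33	-0.18	3.90	6.24	4.11	0.73	0.04	3.85
VEST4 rankscore	33.49	1.42	0.73	4.05	-0.35	0.67	1.14	3.43	0.09	0.22	0.74	2.07	0.41	2.48	9.21	3.14	1.37	0.19	3.58
LRT converted rankscore	35.81	1.68	0.46	5.80	0.23	-0.63	1.45	3.13	-0.05	-0.52	0.23	1.71	0.21	2.37	6.84	3.99	1.06	0.45	3.57
"""


def load_published_slp_table() -> pd.DataFrame:
    """Published SLP matrix: predictors x 18 genes, indexed by predictor.

    The ``published_average`` column carries the per-predictor mean SLP as
    printed in the source table (rounded to 2 decimals there).
    """
    return pd.read_csv(io.StringIO(_SLP_TABLE), sep="\t", index_col="predictor")


def published_mean_slp() -> pd.Series:
    """The published per-predictor average SLPs."""
    return load_published_slp_table()["published_average"]


def load_published_gene_pairs() -> pd.DataFrame:
    """Gene, phenotype and association direction for the 18 benchmark pairs."""
    return pd.read_csv(io.StringIO(_GENE_INFO), sep="\t")
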