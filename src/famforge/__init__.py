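"""famforge: gene-family discovery, characterization and evolution toolkit.

Subpackages
-----------
synthetic_data   truth-tagged synthetic proteomes, duplicate gene sets,
                 expression matrices and phenotype grade tables
profile_search   local alignment, PSSM construction, iterative profile
                 expansion and greedy identity clustering
domain_annot     progressive MSA, conserved-site statistics and C-terminal
                 domain architecture annotation
evolution        duplicate detection, tandem classification, NG86 Ka/Ks and
                 reciprocal-best-hit ortholog pairing
expression       median-of-ratios normalization, hierarchical clustering,
                 expression-breadth categories and 2^-ddCt quantification
phenotype        morbidity and disease-index scoring
io_cli           FASTA/GFF3/TSV readers and writers, run configuration and
                 the ``famforge`` command line
"""

__version__ = "0.1.0"

_SUBMODULES = {
    "domain_annot",
    "evolution",
    "expression",
    "io_cli",
    "phenotype",
    "profile_search",
    "synthetic_data",
}


def __getattr__(name):
    if name in _SUBMODULES:
        import importlib

        return importlib.import_module(f"famforge.{name}")
    raise AttributeError(f"module 'famforge' has no attribute {name!r}")
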