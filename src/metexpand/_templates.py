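"""Embedded template molecules for the synthetic study generator.

Roughly a hundred curated (name, SMILES) pairs of metabolites reported in
marine microalgae and their associated bacteria, spanning the four
superclasses that dominate diatom metabolomes: organic acids and
derivatives, organoheterocyclic compounds, lipids and lipid-like
molecules, and organic oxygen compounds. All structures are CHNOPS-only
and parseable by RDKit; structures are pairwise distinct by canonical
SMILES.

Note that some chemically distinct metabolites (e.g. saturated fatty-acid
chain homologs, or sugar stereoisomers) share a radius-2 achiral Morgan
fingerprint; the study generator samples at most one member of such a
collision group per study so that fingerprint-based ground truth stays
exact.
"""

TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "Organic acids and derivatives": [
        ("glycine", "NCC(=O)O"),
        ("L-alanine", "C[C@H](N)C(=O)O"),
        ("L-serine", "OC[C@H](N)C(=O)O"),
        ("L-proline", "OC(=O)[C@@H]1CCCN1"),
        ("L-valine", "CC(C)[C@H](N)C(=O)O"),
        ("L-leucine", "CC(C)C[C@H](N)C(=O)O"),
        ("L-isoleucine", "CC[C@H](C)[C@H](N)C(=O)O"),
        ("L-threonine", "C[C@@H](O)[C@H](N)C(=O)O"),
        ("L-methionine", "CSCC[C@H](N)C(=O)O"),
        ("L-glutamic acid", "N[C@@H](CCC(=O)O)C(=O)O"),
        ("L-aspartic acid", "N[C@@H](CC(=O)O)C(=O)O"),
        ("L-glutamine", "NC(=O)CC[C@H](N)C(=O)O"),
        ("L-asparagine", "NC(=O)C[C@H](N)C(=O)O"),
        ("L-lysine", "NCCCC[C@H](N)C(=O)O"),
        ("L-arginine", "N=C(N)NCCC[C@H](N)C(=O)O"),
        ("L-phenylalanine", "N[C@@H](Cc1ccccc1)C(=O)O"),
        ("L-tyrosine", "N[C@@H](Cc1ccc(O)cc1)C(=O)O"),
        ("L-tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O"),
        ("L-histidine", "N[C@@H](Cc1c[nH]cn1)C(=O)O"),
        ("L-cysteine", "N[C@@H](CS)C(=O)O"),
        ("pipecolic acid", "OC(=O)C1CCCCN1"),
        ("4-hydroxyproline", "O[C@H]1CN[C@@H](C1)C(=O)O"),
        ("betaine", "C[N+](C)(C)CC(=O)[O-]"),
        ("L-ornithine", "NCCC[C@H](N)C(=O)O"),
        ("L-citrulline", "NC(=O)NCCC[C@H](N)C(=O)O"),
        ("malic acid", "OC(CC(=O)O)C(=O)O"),
        ("citric acid", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
        ("succinic acid", "OC(=O)CCC(=O)O"),
        ("fumaric acid", "OC(=O)/C=C/C(=O)O"),
        ("malonic acid", "OC(=O)CC(=O)O"),
        ("malonamide", "NC(=O)CC(N)=O"),
        ("lactic acid", "CC(O)C(=O)O"),
        ("pyruvic acid", "CC(=O)C(=O)O"),
        ("taurine", "NCCS(=O)(=O)O"),
        ("creatine", "CN(CC(=O)O)C(=N)N"),
        ("N,N-dimethylarginine", "CN(C)C(=N)NCCC[C@H](N)C(=O)O"),
        ("methionine sulfoxide", "CS(=O)CC[C@H](N)C(=O)O"),
        ("2-oxoglutaric acid", "OC(=O)CCC(=O)C(=O)O"),
        ("sebacic acid", "OC(=O)CCCCCCCCC(=O)O"),
        ("4-oxosebacic acid", "OC(=O)CCC(=O)CCCCCC(=O)O"),
        (
            "chlorogenic acid",
            "O[C@@H]1C[C@](O)(C[C@H](OC(=O)/C=C/c2ccc(O)c(O)c2)[C@H]1O)C(=O)O",
        ),
        ("4-hydroxycinnamic acid", "OC(=O)/C=C/c1ccc(O)cc1"),
        ("cysteinolic acid", "NC(CO)CS(=O)(=O)O"),
        ("10-cyanodecanoic acid", "N#CCCCCCCCCCC(=O)O"),
    ],
    "Organoheterocyclic compounds": [
        ("adenine", "Nc1ncnc2[nH]cnc12"),
        ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
        ("hypoxanthine", "O=c1[nH]cnc2[nH]cnc12"),
        ("xanthine", "O=c1[nH]c(=O)c2[nH]cnc2[nH]1"),
        ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
        ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
        ("cytosine", "Nc1cc[nH]c(=O)n1"),
        ("indole", "c1ccc2[nH]ccc2c1"),
        ("indole-3-acetic acid", "OC(=O)Cc1c[nH]c2ccccc12"),
        ("tryptamine", "NCCc1c[nH]c2ccccc12"),
        ("serotonin", "NCCc1c[nH]c2ccc(O)cc12"),
        ("nicotinic acid", "OC(=O)c1cccnc1"),
        ("nicotinamide", "NC(=O)c1cccnc1"),
        ("pyridoxine", "Cc1ncc(CO)c(CO)c1O"),
        ("caffeine", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
        ("theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
        ("uric acid", "O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1"),
        ("histamine", "NCCc1c[nH]cn1"),
        ("melatonin", "COc1ccc2[nH]cc(CCNC(C)=O)c2c1"),
        ("allantoin", "NC(=O)NC1NC(=O)NC1=O"),
        ("biotin", "O=C(O)CCCC[C@@H]1SC[C@@H]2NC(=O)N[C@H]12"),
        ("adenosine", "Nc1ncnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O"),
        (
            "guanosine",
            "Nc1nc2c(ncn2[C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)[nH]1",
        ),
        ("cyclic AMP", "Nc1ncnc2c1ncn2[C@@H]1O[C@@H]2COP(=O)(O)O[C@H]2[C@H]1O"),
        ("pterin", "Nc1nc2nccnc2c(=O)[nH]1"),
        ("imidazole-4-acetic acid", "OC(=O)Cc1c[nH]cn1"),
        ("kynurenine", "N[C@@H](CC(=O)c1ccccc1N)C(=O)O"),
        ("nicotinamide N-oxide", "NC(=O)c1ccc[n+]([O-])c1"),
        ("pyridoxal", "Cc1ncc(CO)c(C=O)c1O"),
    ],
    "Lipids and lipid-like molecules": [
        ("octanoic acid", "CCCCCCCC(=O)O"),
        ("oleic acid", "CCCCCCCC/C=C\\CCCCCCCC(=O)O"),
        ("linoleic acid", "CCCCC/C=C\\C/C=C\\CCCCCCCC(=O)O"),
        (
            "eicosapentaenoic acid",
            "CC/C=C\\C/C=C\\C/C=C\\C/C=C\\C/C=C\\CCCC(=O)O",
        ),
        ("arachidonic acid", "CCCCC/C=C\\C/C=C\\C/C=C\\C/C=C\\CCCC(=O)O"),
        ("eicosatrienoic acid", "CCCCCCCC/C=C\\C/C=C\\C/C=C\\CCCC(=O)O"),
        ("hexadecanamide", "CCCCCCCCCCCCCCCC(N)=O"),
        ("9-octadecenamide", "CCCCCCCC/C=C\\CCCCCCCC(N)=O"),
        ("5-eicosenamide", "CCCCCCCCCCCCCC/C=C\\CCCC(N)=O"),
        ("7-oxoheptadecanoic acid", "CCCCCCCCCCC(=O)CCCCCC(=O)O"),
        ("myristic monoethanolamide", "CCCCCCCCCCCCCC(=O)NCCO"),
        ("L-carnitine", "C[N+](C)(C)C[C@H](O)CC(=O)[O-]"),
        ("O-acetyl-L-carnitine", "CC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
        ("O-propanoyl-L-carnitine", "CCC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
        ("O-butanoyl-L-carnitine", "CCCC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
        ("isovalerylcarnitine", "CC(C)CC(=O)O[C@H](CC(=O)[O-])C[N+](C)(C)C"),
        ("1-palmitoylglycerol", "CCCCCCCCCCCCCCCC(=O)OCC(O)CO"),
        (
            "sn-glycero-3-phosphocholine",
            "C[N+](C)(C)CCOP(=O)([O-])OC[C@@H](O)CO",
        ),
        (
            "alpha-tocopherol",
            "Cc1c(C)c2c(c(C)c1O)CC[C@@](C)(CCC[C@H](C)CCC[C@H](C)CCCC(C)C)O2",
        ),
        ("12-oxododecanoic acid", "O=CCCCCCCCCCCC(=O)O"),
    ],
    "Organic oxygen compounds": [
        ("D-glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
        ("D-fructose", "OCC1(O)OC[C@@H](O)[C@@H](O)[C@@H]1O"),
        ("D-ribose", "OC[C@H]1OC(O)[C@H](O)[C@@H]1O"),
        ("D-xylose", "O[C@@H]1CO[C@@H](O)[C@H](O)[C@H]1O"),
        ("L-fucose", "C[C@@H]1OC(O)[C@@H](O)[C@H](O)[C@@H]1O"),
        (
            "sucrose",
            "OC[C@H]1O[C@@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)"
            "[C@@H](O)[C@@H]1O",
        ),
        (
            "maltose",
            "OC[C@H]1O[C@H](O[C@H]2[C@H](O)[C@@H](O)C(O)O[C@@H]2CO)"
            "[C@H](O)[C@@H](O)[C@@H]1O",
        ),
        (
            "trehalose",
            "OC[C@H]1O[C@H](O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)"
            "[C@H](O)[C@@H](O)[C@@H]1O",
        ),
        (
            "3-alpha-mannobiose",
            "OC[C@H]1O[C@@H](O)[C@@H](O)[C@@H](O[C@@H]2O[C@H](CO)[C@@H](O)"
            "[C@H](O)[C@@H]2O)[C@@H]1O",
        ),
        ("gluconic acid", "OC[C@@H](O)[C@@H](O)[C@H](O)[C@@H](O)C(=O)O"),
        ("glucuronic acid", "O[C@H]1OC([C@@H](O)[C@H](O)[C@H]1O)C(=O)O"),
        ("ascorbic acid", "OC[C@H](O)[C@H]1OC(=O)C(O)=C1O"),
        ("glycerol", "OCC(O)CO"),
        ("myo-inositol", "OC1C(O)C(O)C(O)C(O)C1O"),
        ("D-mannitol", "OC[C@@H](O)[C@@H](O)[C@H](O)[C@H](O)CO"),
        ("erythritol", "OC[C@H](O)[C@H](O)CO"),
        ("D-allulose", "OCC(=O)[C@@H](O)[C@@H](O)[C@H](O)CO"),
        ("L-sorbose", "OC[C@@H](O)[C@H](O)[C@@H](O)C(=O)CO"),
        ("dihydroxyacetone", "OCC(=O)CO"),
        (
            "glucose-1-phosphate",
            "OC[C@H]1O[C@H](OP(=O)(O)O)[C@H](O)[C@@H](O)[C@@H]1O",
        ),
        ("phloroglucinol", "Oc1cc(O)cc(O)c1"),
    ],
}

#: default superclass sampling weights, loosely following the composition
#: of the expanded diatom catalog (organic acids most prevalent, then
#: organoheterocyclics, lipids and organic oxygen compounds)
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "Organic acids and derivatives": 0.35,
    "Organoheterocyclic compounds": 0.25,
    "Lipids and lipid-like molecules": 0.22,
    "Organic oxygen compounds": 0.18,
}
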