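"""Default perturbation barcode design.

Eight perturbation plasmids, each tagged with an array of redeployed 50-nt
RTL-probe capture barcodes (one olfactory-, one taste- and one
vomeronasal-receptor derived sequence per triplet; some plasmids carry two
arrays plus an extra single barcode, for 38 barcodes in total).  The barcode
identifier is the endogenous transcript whose capture probe was redeployed.
"""

from __future__ import annotations

import pandas as pd

from .data import BarcodeDesign

# plasmid -> ordered (barcode_id, 50-nt capture sequence)
DEFAULT_BARCODES: dict[str, list[tuple[str, str]]] = {
    "Myc": [
        ("Olfr103", "TGGGAGTGAGAGACATACAAGAACCACAGCCCTTTCTCTTTGCTATTTTC"),
        ("Tas2r102", "AACACAAGTGTGAATACCATGAGCAATGACCTTGCAATGTGGACCGAGCT"),
        ("Vmn1r1", "TAAAAGGCAGTGTCAGTACCTTCACAACACCAGCATTTCCCGCAAAGCAT"),
        ("Olfr1018", "CAGTTCCATGGTTATCAATGTTCTCACCTTGAGTTTGCCCTACTGTGGAC"),
        ("Tas2r118", "TTATTGGCACTGTGTTTGATAAGAAATCTTGGTTCTGGGTCTGCGAAGCT"),
        ("Vmn1r174", "ACTTCAACCAGAGGCCAGAGCAGCAAACACAATTCTCATGCTGATGATCA"),
        ("Olfr1", "TGGCCAGCATCTTTCTTGTCCTTCCATTTGCACTCATTACCATGTCCTAT"),
    ],
    "mtCtnnb1": [
        ("Olfr1000", "GGCACAGTAGGTATGTTCACTGGTCTGATAATTCTGGGGTCCTATGTATG"),
        ("Tas2r103", "TGTCACTAATCACAGGGTTCTTGGTATCATTATTGGACCCAGCTTTATTG"),
        ("Vmn1r178", "GTCTCTTCATGAGTCATTTCAGTAAAGTTTTTGCTGCAGGATTCCCCACT"),
        ("Olfr1019", "TGCTTGGTCCTAATGCTGGGCTCTTACTTCGCTGGCCTAGTGAGTTTAGT"),
        ("Tas2r119", "GATATCCAGGTTGGTGCCATGGCTGATCCTGGCATCTGTGGTCTATGTAA"),
        ("Vmn1r175", "AGTACAAACATGTGCTCCACCTGCTTTCTGAGCACTTATCAGCTTGTCAC"),
    ],
    "NICD": [
        ("Olfr1006", "AGGGAACATGTTGCTGGTTGTTTTAATCCGAATTGATTCTAGACTGCATA"),
        ("Tas2r105", "GACCTCGGAGATGTACTGGGAGAAAAGGCAATTCACTATTAACTACGTTT"),
        ("Vmn1r139", "AAGCATTGGCAAGTCACAGGCAAAGAGTGACACAGAGACGTTCCTCAATT"),
    ],
    "VEGFA": [
        ("Olfr1002", "AGGCCTTATAAGCACTGTGGTCCATACTACTTCTGCATTTATTCTTCCAT"),
        ("Tas2r104", "TAACGTGGCTAGCTTCCTTTCCGCTAGCTGTGAAGGTCATTAAAGATGTT"),
        ("Vmn1r12", "ACTACATTGTCAGGAGCTTGATTTTAACTGTGACAACTTCCAGGGATATG"),
    ],
    "shPten": [
        ("Olfr1013", "GTACACATTGACTTTGATGGGAAATAGCTCCCTCATTATGTTAATCTGCA"),
        ("Tas2r110", "ACTAGTGAATATCATGGACTGGACCAAGAGAAGAAGCATTTCATCAGCGG"),
        ("Vmn1r170", "TGATTCTCCTGAACAGACACCACCACAGACTGCAGCATATTCAATCCACA"),
        ("Olfr1015", "TGTCTATGTGAAAATCCTTTCCAGTATGGTGGGCTTCACTGTCCTCTCAA"),
        ("Tas2r114", "TGTAATTTGTCTGTTAATCCCAGAAAGCAACTTGTTATTCATGTTTGGTT"),
        ("Vmn1r172", "GGAAGTAAATGCCCAGAGAGTCTTCAAAGGAAGACAGTCATAGCTGTTTT"),
    ],
    "shRen": [
        ("Olfr1008", "CCAGGCTCTGCTATTCACCAGTAAAATTTTCACATTAACTTTCTGTGGCT"),
        ("Tas2r106", "AAGGCACTGAAGCAATTAAAATGCCATAAGAAAGACAAGGACGTCAGAGT"),
        ("Vmn1r157", "CAGATCCTCTTGCTTTGCCATTTTGAGGTTGGGACCGTGGCCAATGTCTT"),
    ],
    "shTrp53": [
        ("Olfr1009", "CCAGAGACTCTGCATACAGCTGGTGATCGGACCCTATGCTGTTGGCTTTT"),
        ("Tas2r107", "GCTCTCTAAGATCGGTTTCATTCTCATTGGCTTGGCGATTTCCAGAATTG"),
        ("Vmn1r167", "GTTTCAGTATAGGCATGCGCATCTTATCATTTGCCCATGATGGAGTGTTC"),
        ("Olfr1014", "TTGCTGTGTATGCATTAACTGTGTTAGGAAACAGCACCCTCATTGTGTTG"),
        ("Tas2r113", "GATCAATCATTGTAACTTTTGGCTTACTGCAAACTTGAGCATCCTTTATT"),
        ("Vmn1r171", "AACAGCACTGCCCTCATGATCACTATTCCGTTGACCAATGAAGTTGTCTC"),
        ("Olfr107", "TTACTGCTTTCTTGCTCAGACACTCACCTCAGTGAGGGCCTGATGATGGC"),
    ],
    "shKmt2c": [
        ("Olfr1012", "ATCTACTCTCGGCCAAGTTCCAGTTATTCCTTGGAAAGGGATAAAATGGT"),
        ("Tas2r109", "TTCTAGAATTTTCCTGCTCTGGTTCATGCTAGTAGGTTTTCCAATTAGCT"),
        ("Vmn1r169", "GGTACCTGGGGTAGGGTGATGCTCCATGGAAGAGCCCCCAAATTTGTGAG"),
    ],
}


def default_design() -> BarcodeDesign:
    """The 8-plasmid, 38-barcode default design."""
    rows = [
        {"plasmid_id": plasmid, "barcode_id": bc, "sequence": seq}
        for plasmid, pairs in DEFAULT_BARCODES.items()
        for bc, seq in pairs
    ]
    return BarcodeDesign.from_table(pd.DataFrame(rows))


def triplet_design(n_plasmids: int, barcodes_per_plasmid: int = 3) -> BarcodeDesign:
    """A synthetic design with ``n_plasmids`` plasmids of equal-size barcode arrays."""
    rows = [
        {"plasmid_id": f"plasmid{g}", "barcode_id": f"bc{g}_{j}"}
        for g in range(n_plasmids)
        for j in range(barcodes_per_plasmid)
    ]
    return BarcodeDesign.from_table(pd.DataFrame(rows))
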