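"""Regenerate the shipped flavonoid knowledge directory.

The residue/domain/specificity tables encode published knowledge about
flavonoid biosynthesis enzymes (chalcone-synthase diagnostics Q166/Q167,
the malonyl-CoA-binding motif at 313-329 on the reference, and the DFR
substrate-specificity site at position 3 of the 26-aa substrate-binding
domain).  The bait FASTA files are *synthetic* stand-ins generated at a
fixed seed: families sharing descent with the documented diagnostic
residues planted, sized like the real enzymes, for demonstration and
testing without downloads.
"""

from pathlib import Path

import numpy as np

from pathscreen.fixtures import make_family, _mutate
from pathscreen.seqkit import write_fasta

OUT = Path(__file__).resolve().parent.parent / "src" / "pathscreen" / "data" / "flavonoid"

SEED = 20200827


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # CHS and STS share descent; they differ at the diagnostic positions
    _, anc_truth = make_family(2, 395, 0.0, [], seed=SEED, family="ANC")
    ancestor = anc_truth.families["ANC"]["ancestor"]
    chs, _ = make_family(
        8, 395, 0.12, [(166, "Q"), (167, "Q")], seed=SEED + 1, family="CHS_synthetic",
        conserved_spans=[(313, 329)], ancestor=ancestor,
    )
    sts_anc = _mutate(np.random.default_rng(SEED + 2), ancestor, 0.22, {166, 167})
    sts, _ = make_family(
        8, 395, 0.12, [(166, "Q"), (167, "H")], seed=SEED + 3, family="STS_synthetic",
        ancestor=sts_anc,
    )
    dfr, _ = make_family(
        8, 340, 0.12, [(133, "N")], seed=SEED + 4, family="DFR_synthetic",
    )
    write_fasta(chs, OUT / "synthetic_CHS_baits.fasta")
    write_fasta(sts, OUT / "synthetic_STS_baits.fasta")
    write_fasta(dfr, OUT / "synthetic_DFR_baits.fasta")

    (OUT / "CHS.residues.txt").write_text(
        "# chalcone synthase: diagnostic residues and malonyl-CoA-binding motif\n"
        "166 Q CHS-diagnostic-Q166\n"
        "167 Q CHS-diagnostic-Q167\n"
        "313-329 malonyl-CoA-binding-motif 0.6\n"
    )
    (OUT / "DFR.residues.txt").write_text(
        "# dihydroflavonol 4-reductase: substrate-specificity annotation\n"
        "@anchor substrate-binding 131 26\n"
        "133 NDLA DFR-substrate-site\n"
        "@spec substrate-binding 3 N accepts dihydrokaempferol, dihydroquercetin, dihydromyricetin\n"
        "@spec substrate-binding 3 D reduced dihydrokaempferol acceptance\n"
        "@spec substrate-binding 3 L dihydrokaempferol preference, reduced dihydromyricetin processing\n"
        "@spec substrate-binding 3 A dihydrokaempferol preference, reduced dihydromyricetin processing\n"
    )
    (OUT / "config.tsv").write_text(
        "CHS\tsynthetic_CHS_baits.fasta\tCHS_synthetic_1\tCHS.residues.txt\n"
        "STS\tsynthetic_STS_baits.fasta\tSTS_synthetic_1\t\n"
        "DFR\tsynthetic_DFR_baits.fasta\tDFR_synthetic_1\tDFR.residues.txt\n"
    )
    print(f"shipped data written to {OUT}")


if __name__ == "__main__":
    main()
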