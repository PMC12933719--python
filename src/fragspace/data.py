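"""Bundled drug-like source molecules for synthetic spaces and benchmarks.

A hand-curated set of well-known small-molecule drugs and natural products,
kept in-repo so that space generation and benchmarking need no downloads.
``bundled_molecules`` filters the raw list to molecules that parse, have at
most one violation of the rule-of-five criteria, and contain at least one
cuttable acyclic single bond.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

__all__ = ["SOURCE_SMILES", "bundled_molecules", "rule_of_five_violations"]

SOURCE_SMILES: list[str] = [
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",  # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",  # naproxen
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",  # diazepam
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",  # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",  # propranolol
    "COCCc1ccc(OCC(O)CNC(C)C)cc1",  # metoprolol
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",  # lidocaine
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",  # procaine
    "CCOC(=O)c1ccc(N)cc1",  # benzocaine
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",  # salbutamol
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",  # warfarin
    "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",  # celecoxib
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",  # sulfamethoxazole
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",  # trimethoprim
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",  # chlorpromazine
    "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",  # haloperidol
    "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",  # fluoxetine
    "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",  # sertraline
    "CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21",  # citalopram
    "COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1",  # venlafaxine
    "COc1cccc(C2(O)CCCCC2CN(C)C)c1",  # tramadol
    "CN(C)CCC=C1c2ccccc2CCc2ccccc21",  # amitriptyline
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",  # imipramine
    "CN(C)CCOC(c1ccccc1)c1ccccc1",  # diphenhydramine
    "CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1",  # chlorpheniramine
    "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1",  # loratadine
    "O=C(O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1",  # cetirizine
    "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1",  # omeprazole
    "Cc1c(OCC(F)(F)F)ccnc1CS(=O)c1nc2ccccc2[nH]1",  # lansoprazole
    "CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1",  # ketoprofen
    "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl",  # diclofenac
    "Cc1cccc(Nc2ccccc2C(=O)O)c1C",  # mefenamic acid
    "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",  # indomethacin
    "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1",  # tolbutamide
    "Cc1ncc([N+](=O)[O-])n1CCO",  # metronidazole
    "NNC(=O)c1ccncc1",  # isoniazid
    "NC(=O)c1cnccn1",  # pyrazinamide
    "NC(=O)c1cccnc1",  # nicotinamide
    "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12",  # chloroquine
    "Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1",  # dapsone
    "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",  # phenytoin
    "NC(=O)N1c2ccccc2C=Cc2ccccc21",  # carbamazepine
    "Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1",  # lamotrigine
    "NCC1(CC(=O)O)CCCCC1",  # gabapentin
    "NCC(CC(=O)O)c1ccc(Cl)cc1",  # baclofen
    "Nc1ccc(S(N)(=O)=O)cc1",  # sulfanilamide
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",  # theophylline
    "CCOc1ccc(NC(C)=O)cc1",  # phenacetin
    "COc1cc(CCN)cc(OC)c1OC",  # mescaline
    "CC(N)Cc1ccccc1",  # amphetamine
    "CNC(C)C(O)c1ccccc1",  # ephedrine
    "CN1CCCC1c1cccnc1",  # nicotine
    "COc1ccc2[nH]cc(CCNC(C)=O)c2c1",  # melatonin
    "NCCc1c[nH]c2ccc(O)cc12",  # serotonin
    "NCCc1ccc(O)c(O)c1",  # dopamine
    "NCCc1ccc(O)cc1",  # tyramine
    "COc1ccc(Cc2nccc3cc(OC)c(OC)cc23)cc1OC",  # papaverine
    "COc1cc2nc(N3CCN(C(=O)c4ccco4)CC3)nc(N)c2cc1OC",  # prazosin
]


def rule_of_five_violations(mol: Chem.Mol) -> int:
    """Number of violated rule-of-five criteria (MW, logP, HBD, HBA)."""
    violations = 0
    if Descriptors.MolWt(mol) > 500:
        violations += 1
    if Crippen.MolLogP(mol) > 5:
        violations += 1
    if Lipinski.NumHDonors(mol) > 5:
        violations += 1
    if Lipinski.NumHAcceptors(mol) > 10:
        violations += 1
    return violations


def _has_cuttable_bond(mol: Chem.Mol) -> bool:
    return any(
        b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
        for b in mol.GetBonds()
    )


def bundled_molecules(max_violations: int = 1) -> list[str]:
    """Curated SMILES passing the rule-of-five filter, with a cuttable bond."""
    keep = []
    for smi in SOURCE_SMILES:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if rule_of_five_violations(mol) > max_violations:
            continue
        if not _has_cuttable_bond(mol):
            continue
        keep.append(smi)
    return keep
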