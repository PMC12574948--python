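"""Dev script: build the packaged IMGT-numbered V-domain consensus references
and MHC reference FASTA.  Run once; outputs are committed under src/tcrkit/data.

Design: each V consensus occupies every IMGT position 1..128 (no gaps), so the
position index IS the IMGT number.  Conserved residues: Cys 23, Trp 41,
Cys 104, Phe 118 (F/W-G-X-G motif of FR4).
Region lengths: FR1 26, CDR1 12, FR2 17, CDR2 10, FR3 39, CDR3 13, FR4 11.
"""
import csv, pathlib

REG_LENS = {"FR1": 26, "CDR1": 12, "FR2": 17, "CDR2": 10, "FR3": 39, "CDR3": 13, "FR4": 11}

ALPHA = {
    "FR1":  "AQSVTQLDSHVSVSEGTPVLLRCNYS",
    "CDR1": "DRGSQSYSFFWY",
    "FR2":  "QHWYRQHPNKGLQLLLK",
    "CDR2": "YTSAATLVKG",
    "FR3":  "SRFEAEFKKSETSFHLRKPSVHISDTAEYFSAVTLNKAC",
    "CDR3": "AVSDLEPNSSASK",
    "FR4":  "FGSGTRLSIRP",
}
BETA = {
    "FR1":  "DAGVIQSPRHEVTEMGQEVTLRCKPI",
    "CDR1": "SGHTALYWYQQT",
    "FR2":  "LGWYRQTLGQGPEFLTY",
    "CDR2": "FQNEAQLEKS",
    "FR3":  "RLLSDRFSAERPKGSFSTLEIQRTEQGDSAMYLSAASSC",
    "CDR3": "ASSLRGATNEKLF",
    "FR4":  "FGPGTRLTVLE",
}

# gamma/delta: start from alpha/beta scaffolds and substitute a deterministic
# set of framework positions (anchors and conserved motif untouched) so the
# four loci are mutually distinguishable by alignment score.
SUB = {"A": "G", "Q": "E", "S": "T", "V": "I", "L": "M", "K": "R", "E": "D",
       "T": "S", "D": "N", "H": "Y", "N": "Q", "R": "K", "I": "V", "G": "A"}
PROTECT = {23, 41, 104, 118, 119, 120, 121}

def mutate(regions, step):
    out, pos = {}, 0
    for reg in ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]:
        s = list(regions[reg])
        for i in range(len(s)):
            pos += 1
            if pos in PROTECT:
                continue
            if pos % step == 0:
                s[i] = SUB.get(s[i], s[i])
        out[reg] = "".join(s)
    return out

GAMMA = mutate(ALPHA, 3)
DELTA = mutate(BETA, 3)

LOCI = {"TCR_ALPHA": ALPHA, "TCR_BETA": BETA, "TCR_GAMMA": GAMMA, "TCR_DELTA": DELTA}

data = pathlib.Path(__file__).resolve().parents[1] / "src" / "tcrkit" / "data"
data.mkdir(parents=True, exist_ok=True)

with open(data / "tcr_v_consensus.csv", "w", newline="") as fh:
    w = csv.writer(fh)
    w.writerow(["locus", "imgt_number", "region", "aa"])
    for locus, regions in LOCI.items():
        pos = 0
        for reg in ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"]:
            seq = regions[reg]
            assert len(seq) == REG_LENS[reg], (locus, reg, len(seq))
            for aa in seq:
                pos += 1
                w.writerow([locus, pos, reg, aa])
        assert pos == 128
        full = "".join(regions[r] for r in ["FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4"])
        assert full[22] == "C" and full[103] == "C" and full[40] == "W" and full[117] == "F", locus

# MHC references: G-domain level sequences (class I alpha1+alpha2 ~180 aa,
# beta-2 microglobulin, class II alpha1 / beta1 domains).
MHC = {
    "MHC1_HEAVY": (
        "GSHSMRYFFTSVSRPGRGEPRFIAVGYVDDTQFVRFDSDAASQRMEPRAPWIEQEGPEYWDGETRKVKAHSQTHRVDLGTLRGYYNQSEAGSHTVQRMYGCDVGSDWRFLRGYHQYAYDGKDYIALKEDLRSWTAADMAAQTTKHKWEAAHVAEQLRAYLEGTCVEWLRRYLENGKETLQ"
    ),
    "B2M": (
        "IQRTPKIQVYSRHPAENGKSNFLNCYVSGFHPSDIEVDLLKNGERIEKVEHSDLSFSKDWSFYLLYYTEFTPTEKDEYACRVNHVTLSQPKIVKWDRDM"
    ),
    "MHC2_ALPHA": (
        "IKEEHVIIQAEFYLNPDQSGEFMFDFDGDEIFHVDMAKKETVWRLEEFGRFASFEAQGALANIAVDKANLEIMTKRSNYTPITN"
    ),
    "MHC2_BETA": (
        "GDTRPRFLWQLKFECHFFNGTERVRLLERCIYNQEESVRFDSDVGEYRAVTELGRPDAEYWNSQKDLLEQRRAAVDTYCRHNYGVGESFT"
    ),
}
with open(data / "mhc_references.fasta", "w") as fh:
    for name, seq in MHC.items():
        fh.write(f">{name}\n{seq}\n")

print("lengths:", {k: len(v) for k, v in MHC.items()})
print("ok")
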