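# Named glycan motif templates: name	IUPAC-condensed (canonical form).
# Definitions follow standard glycobiology usage (Lewis/blood-group antigens,
# milk oligosaccharides, N-/O-glycan cores).
LacNAc	Gal(b1-4)GlcNAc
LacdiNAc	GalNAc(b1-4)GlcNAc
Lactose	Gal(b1-4)Glc
Chitobiose	GlcNAc(b1-4)GlcNAc
TnAntigen	GalNAc
TAntigen	Gal(b1-3)GalNAc
LewisA	Gal(b1-3)[Fuc(a1-4)]GlcNAc
LewisB	Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc
LewisX	Gal(b1-4)[Fuc(a1-3)]GlcNAc
LewisY	Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc
SialylLewisA	Neu5Ac(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc
SialylLewisX	Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc
Htype1	Fuc(a1-2)Gal(b1-3)GlcNAc
Htype2	Fuc(a1-2)Gal(b1-4)GlcNAc
BloodGroupA	GalNAc(a1-3)[Fuc(a1-2)]Gal
BloodGroupB	Gal(a1-3)[Fuc(a1-2)]Gal
2FL	Fuc(a1-2)Gal(b1-4)Glc
3FL	Gal(b1-4)[Fuc(a1-3)]Glc
3SL	Neu5Ac(a2-3)Gal(b1-4)Glc
6SL	Neu5Ac(a2-6)Gal(b1-4)Glc
LNT	Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc
LNnT	Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc
NGlycanCore	Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc
Man5	Man(a1-3)[Man(a1-6)]Man(a1-6)[Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc
G0	GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc
G2	Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc
Core1	Gal(b1-3)GalNAc
Core2	Gal(b1-3)[GlcNAc(b1-6)]GalNAc
Core3	GlcNAc(b1-3)GalNAc
SialylTn	Neu5Ac(a2-6)GalNAc
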