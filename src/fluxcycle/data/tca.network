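# Default TCA-cycle network for pulse-chase tracing of proliferating cells.
#
# Single-pool simplification (no cytosol/mitochondria split). Glycolysis is
# collapsed into a pyruvate source whose labeling follows the glucose tracer;
# glutamine enters via glutamate. CO2 is an explicit 1-carbon source/sink and
# is never balanced. Succinate and fumarate carry the two-fold rotational
# symmetry flag. Pool sizes are in arbitrary per-cell units.

[metabolites]
GlcPyr, 3, 1.0, source, 0.0
GlnSrc, 5, 1.0, source, 0.0
CO2, 1, 1.0, source, 0.0
Pyr, 3, 2.0, balanced, 0.0
AcCoA, 2, 0.5, balanced, 0.0
Cit, 6, 3.0, balanced, 0.0
AKG, 5, 2.0, balanced, 0.0
Suc, 4, 1.0, balanced, 0.0, symmetric
Fum, 4, 0.8, balanced, 0.0, symmetric
Mal, 4, 1.5, balanced, 0.0
OAA, 4, 0.4, balanced, 0.0
Glu, 5, 4.0, balanced, 0.0
SinkAc, 2, 1.0, sink, 0.0
SinkOAA, 4, 1.0, sink, 0.0

[reactions]
pyr_in: GlcPyr (abc) -> Pyr (abc)
pdh: Pyr (abc) -> AcCoA (bc) + CO2 (a)
pc: Pyr (abc) + CO2 (d) -> OAA (abcd)
cs: OAA (abcd) + AcCoA (ef) -> Cit (dcbfea)
idh_ox: Cit (abcdef) -> AKG (abcde) + CO2 (f)
idh_red: AKG (abcde) + CO2 (f) -> Cit (abcdef)
akgdh: AKG (abcde) -> Suc (bcde) + CO2 (a)
sdh: Suc (abcd) -> Fum (abcd)
fh: Fum (abcd) -> Mal (abcd)
mdh: Mal (abcd) -> OAA (abcd)
gls: GlnSrc (abcde) -> Glu (abcde)
gdh: Glu (abcde) -> AKG (abcde)
acl: Cit (abcdef) -> AcCoA (ed) + OAA (fcba)
acc_out: AcCoA (ab) -> SinkAc (ab)
oaa_out: OAA (abcd) -> SinkOAA (abcd)
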