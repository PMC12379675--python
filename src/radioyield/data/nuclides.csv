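# Nuclide data for the 176Yb(d,x) production network.
# half_life: value in half_life_unit, or 'stable'.
# The 176mLu and 174mLu half-lives are the consistency-adjusted values of the
# reference scenario (see docs/methods.md); some evaluations list 3.66 d and
# 120.9 d respectively.
# daughter: next member of the (linear) decay chain, empty if stable.
name,element,Z,A,isomer,half_life,half_life_unit,molar_mass,daughter
Yb176,Yb,70,176,,stable,,175.942574,
Yb177,Yb,70,177,,1.911,h,176.945266,Lu177g
Lu177g,Lu,71,177,g,6.647,d,176.943764,Hf177
Lu177m,Lu,71,177,m,160.4,d,176.943764,Hf177
Lu176g,Lu,71,176,g,3.76e10,y,175.942692,Hf176
Lu176m,Lu,71,176,m,3.664,h,175.942692,Hf176
Lu175,Lu,71,175,,stable,,174.940777,
Lu174g,Lu,71,174,g,3.31,y,173.940343,Yb174
Lu174m,Lu,71,174,m,142.2,d,173.940343,Yb174
Hf177,Hf,72,177,,stable,,176.943228,
Hf176,Hf,72,176,,stable,,175.941410,
Yb174,Yb,70,174,,stable,,173.938866,
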