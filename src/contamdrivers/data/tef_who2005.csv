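# WHO 2005 toxic equivalency factors for the 17 laterally (2,3,7,8-) chlorinated
# dibenzo-p-dioxin and dibenzofuran congeners.
# Source: Van den Berg et al. (2006) Toxicol. Sci. 93(2):223-241.
congener,tef
2378-TCDD,1.0
12378-PeCDD,1.0
123478-HxCDD,0.1
123678-HxCDD,0.1
123789-HxCDD,0.1
1234678-HpCDD,0.01
OCDD,0.0003
2378-TCDF,0.1
12378-PeCDF,0.03
23478-PeCDF,0.3
123478-HxCDF,0.1
123678-HxCDF,0.1
123789-HxCDF,0.1
234678-HxCDF,0.1
1234678-HpCDF,0.01
1234789-HpCDF,0.01
OCDF,0.0003
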