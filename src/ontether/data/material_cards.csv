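# Regional hyperelastic material cards for the human posterior eye and optic nerve.
# Reduced-polynomial coefficients C10..C60 and volumetric coefficient D1.
# C10, C20 in MPa as printed; C30..C60 are printed x1e3 and are rescaled by
# 1e-3 on load; D1 in 1/MPa (0 or empty = incompressible, penalty treatment).
# "stiff"/"compliant" are the 95th/5th percentile stress-strain levels of the
# published regional tensile data; "average" is the mean fit.
# The ON neural tissue row is linear elastic (E in MPa, Poisson ratio nu).
region,stiffness,model,C10,C20,C30,C40,C50,C60,D1,E,nu
anterior_sclera,average,reduced_polynomial,0.926,511,-42.6,2260,-59300,594000,0.044,,
equatorial_sclera,average,reduced_polynomial,0.390,252,-11.2,219,,,0.104,,
posterior_sclera,average,reduced_polynomial,0.633,144,-6.08,153,-1930,9550,0.064,,
posterior_sclera,stiff,reduced_polynomial,1.056,179,-7.31,179,-2190,10300,0.038,,
posterior_sclera,compliant,reduced_polynomial,0.069,46,-7.4,4.16,,,0.587,,
peripapillary_sclera,average,reduced_polynomial,0.170,44,-1.43,27.59,-250,845,0.238,,
peripapillary_sclera,stiff,reduced_polynomial,0.060,48,-0.41,21.95,-4300,3510,0.674,,
peripapillary_sclera,compliant,reduced_polynomial,0.080,-0.539,0.00881,-0.0198,15100,,0.400,,
on_sheath,average,reduced_polynomial,0.492,91,-1.78,16.3,,,0.083,,
on_sheath,stiff,reduced_polynomial,0.221,2870,-11.5,280,-3310,14700,0.184,,
on_sheath,compliant,reduced_polynomial,0.127,25,-0.446,2.92,,,0.318,,
lamina_cribrosa,average,reduced_polynomial,0.281,16,-0.0445,0.05,,,0.072,,
on_connective,average,reduced_polynomial,0.626,98,-3.48,70.2,-679,2490,0.065,,
on_connective,stiff,reduced_polynomial,1.226,126,-1.78,8.92,,,0,,
on_connective,compliant,reduced_polynomial,0.160,21.6,-0.311,1.81,,,0,,
on_neural,average,linear_elastic,,,,,,,,0.001195,0.48
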