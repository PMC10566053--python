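id,M0001,M0002,M0003,M0004,M0005,M0006,M0007,M0008,M0009,M0010,M0011,M0012
S0001,64752.495139863844,21906.52983222123,1319.780637622862,13586.380025313376,,933.4478161660428,73249.25509489162,499641.64913851576,,,1347.4487963980616,
S0002,78809.31468347617,9325.993692649636,939.693096140133,904.3986213684514,117924.98549751895,,165774.2982259985,,6240.689782345731,99021.1454372802,841.9248331584832,
S0003,110710.75688501993,,4375.434908142071,1556.002058631332,,,148127.03650670632,,6734.018006052811,462713.53205722856,3247.5993825333053,68355.328406177
S0004,,49608.22095710939,6334.937266494681,3225.7566378123915,,,405773.5040611511,,21042.224768937493,,2213.024770258366,136984.9785607364
S0005,181746.6012530312,,2963.9687896597543,6147.137711981517,,1692.0982029686586,322106.2825775728,,76623.9206290452,,24939.52055993434,
S0006,168594.4557094606,69375.25777166442,3023.8481972492286,27521.34282819479,,,60739.61182165067,,136947.5120621556,,5844.523096517482,95528.31966059328
S0007,80875.52210477066,188789.24249760015,,7059.203723124444,,,171150.0176057152,,10971.06447361728,,2777.108606233498,
S0008,99200.64503119382,164926.24728774524,7273.059699597478,1151.366494178025,,,,,36364.54221240723,,3013.744484352847,108027.72384869902
S0009,120902.05355448311,,5454.083562681709,14198.754323716896,,,67214.84701353198,,16862.85427243513,,2115.215207951036,
S0010,102705.13213159314,198029.61576370813,3555.763084065196,2264.3706475591102,134216.3501010128,,80211.46698459538,,38469.43301561131,,1609.2299402177105,
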