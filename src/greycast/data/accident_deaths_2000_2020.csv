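year,value
2000,120351
2001,130491
2002,139393
2003,137070
2004,136755
2005,127089
2006,112879
2007,101480
2008,91172
2009,83200
2010,79552
2011,75572
2012,71983
2013,69434
2014,68061
2015,66182
2016,43062
2017,37852
2018,34046
2019,29519
2020,27412
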