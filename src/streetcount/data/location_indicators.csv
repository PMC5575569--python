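location,route_type,route,date_surveyed,dogs_per_km,pct_lactating,pct_bcs1,pct_bcs1or2,pct_skin
Bosnia,hotspot,Kljuc,June 2016,9.07,0.0,0.0,0.0,4.2
Bosnia,hotspot,Mrkonjic Grad,June 2016,0.78,0.0,0.0,0.0,
Bosnia,hotspot,Trebinje,September 2016,1.49,11.1,0.0,17.9,10.7
Bogatic municipality Serbia,representative,Badovinci,May 2016,0.855,50.0,0.0,4.2,0.0
Bogatic municipality Serbia,representative,Bogatic,May 2016,0.6,33.3,0.0,11.1,0.0
Bogatic municipality Serbia,representative,Crna Bara,May 2016,0.52,0.0,0.0,0.0,0.0
Bogatic municipality Serbia,representative,Dublje,May 2016,0.145,0.0,0.0,5.6,0.0
Bogatic municipality Serbia,representative,Klenje,May 2016,0.72,0.0,0.0,18.8,0.0
Constanta county Romania,hotspot,Cernavoda,July 2016,4.79,6.8,0.0,8.3,1.4
Constanta county Romania,representative,Agigea,September 2016,6.52,25.9,0.0,44.4,18.5
Panama City Panama,representative,San Miguelito,November-December 2013,5.62,11.1,4.0,38.7,28.2
Panama City Panama,representative,Casco Viejo,November-December 2013,1.07,8.0,2.3,15.9,11.8
Panama City Panama,representative,Juan Diaz,November-December 2013,1.87,0.0,5.1,22.0,22.8
Panama City Panama,representative,Kuna Nega,November-December 2013,5.83,4.6,2.5,18.6,14.5
Puerto Rico,representative,Aguadilla,March 2014,1.13,0.0,0.0,2.6,9.4
Puerto Rico,representative,Fajardo/Ceiba,March 2014,1.73,4.3,0.0,11.3,22.7
Puerto Rico,representative,Toa Alta,March 2014,1.73,0.0,0.0,2.0,9.5
San Jose Costa Rica,representative,San Jose,June 2014,2.59,8.8,0.0,5.6,6.2
San Jose Costa Rica,representative,Heredia Y Belen,June 2014,1.50,0.0,0.0,2.0,6.3
San Jose Costa Rica,representative,Cartago,June 2014,3.09,11.1,1.0,9.0,5.1
San Jose Costa Rica,representative,Alajuela,June 2014,2.28,20.0,1.1,9.6,6.2
San Jose Costa Rica,representative,Rancho Redondo,June 2014,4.09,6.5,1.3,6.4,2.0
Kathmandu Nepal,representative,Zone 1,March 2016,12.30,12.3,0.0,,0.9
Kathmandu Nepal,representative,Zone 2,March 2016,27.14,6.2,0.1,,3.3
Kathmandu Nepal,representative,Zone 3,March 2016,12.28,6.0,0.0,,2.7
Kathmandu Nepal,representative,Zone 4,March 2016,14.41,6.6,0.1,,2.6
Kathmandu Nepal,representative,Zone 5,March 2016,15.66,4.1,0.1,,3.0
Kathmandu Nepal,representative,Zone 6,March 2016,8.40,8.3,0.0,,6.5
Kathmandu Nepal,representative,Zone 7,March 2016,11.37,20.3,0.0,,1.8
Kathmandu Nepal,representative,Zone 8,March 2016,11.76,10.3,0.0,,0.9
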