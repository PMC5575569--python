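location,route_type,route,survey_date,dogs_per_km
Panama City Panama,representative,San Miguelito,2013-12-15,5.62
Panama City Panama,representative,San Miguelito,2014-06-15,5.453
Panama City Panama,representative,San Miguelito,2014-12-15,5.887
Panama City Panama,representative,San Miguelito,2015-10-15,5.73
Panama City Panama,representative,San Miguelito,2016-09-15,5.895
Panama City Panama,representative,Casco Viejo,2013-12-15,1.07
Panama City Panama,representative,Casco Viejo,2014-06-15,1.03
Panama City Panama,representative,Casco Viejo,2014-12-15,0.95
Panama City Panama,representative,Casco Viejo,2015-10-15,0.79
Panama City Panama,representative,Casco Viejo,2016-09-15,0.44
Panama City Panama,representative,Juan Diaz,2013-12-15,1.87
Panama City Panama,representative,Juan Diaz,2014-06-15,2.99
Panama City Panama,representative,Juan Diaz,2014-12-15,2.735
Panama City Panama,representative,Juan Diaz,2015-10-15,2.035
Panama City Panama,representative,Juan Diaz,2016-09-15,1.805
Panama City Panama,representative,Kuna Nega,2013-12-15,5.83
Panama City Panama,representative,Kuna Nega,2014-06-15,4.8167
Panama City Panama,representative,Kuna Nega,2014-12-15,3.883
Panama City Panama,representative,Kuna Nega,2015-10-15,4.73
Panama City Panama,representative,Kuna Nega,2016-09-15,4.435
Puerto Rico,representative,Aguadilla,2014-03-15,1.13
Puerto Rico,representative,Aguadilla,2015-04-15,0.98
Puerto Rico,representative,Aguadilla,2016-03-15,0.60
Puerto Rico,representative,Fajardo/Ceiba,2014-03-15,1.73
Puerto Rico,representative,Fajardo/Ceiba,2015-04-15,1.23
Puerto Rico,representative,Fajardo/Ceiba,2016-03-15,1.25
Puerto Rico,representative,Toa Alta,2014-03-15,1.73
Puerto Rico,representative,Toa Alta,2015-04-15,1.20
Puerto Rico,representative,Toa Alta,2016-03-15,1.04
Bosnia,hotspot,Kljuc,2016-06-15,9.07
Bosnia,hotspot,Kljuc,2016-09-15,7.04
Constanta county Romania,hotspot,Cernavoda,2016-07-15,4.79
Constanta county Romania,hotspot,Cernavoda,2016-10-15,4.34
Kathmandu Nepal,representative,Zone 1,2016-03-15,12.30
Kathmandu Nepal,representative,Zone 1,2016-11-15,15.45
Kathmandu Nepal,representative,Zone 2,2016-03-15,27.14
Kathmandu Nepal,representative,Zone 2,2016-11-15,29.565
Kathmandu Nepal,representative,Zone 3,2016-03-15,12.28
Kathmandu Nepal,representative,Zone 3,2016-11-15,12.675
Kathmandu Nepal,representative,Zone 4,2016-03-15,14.41
Kathmandu Nepal,representative,Zone 4,2016-11-15,13.54
Kathmandu Nepal,representative,Zone 5,2016-03-15,15.66
Kathmandu Nepal,representative,Zone 5,2016-11-15,18.42
Kathmandu Nepal,representative,Zone 6,2016-03-15,8.40
Kathmandu Nepal,representative,Zone 6,2016-11-15,10.905
Kathmandu Nepal,representative,Zone 7,2016-03-15,11.37
Kathmandu Nepal,representative,Zone 7,2016-11-15,14.425
Kathmandu Nepal,representative,Zone 8,2016-03-15,11.76
Kathmandu Nepal,representative,Zone 8,2016-11-15,12.835
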